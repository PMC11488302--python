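"""Clustering of candidate QPPs, robustness screening and representative
selection.

Candidates from the 200 random starts are grouped by agglomerative
clustering (average linkage) on a combined spatiotemporal distance: the
2-norm of (i) a phase-aligned correlation distance between templates and
(ii) a phase-aligned correlation distance between STC traces. The
dendrogram is cut at a fixed combined-distance threshold (default 0.3):
candidates that found the same pattern cohere below ~0.1 in both domains,
hybrid templates mixing two co-occurring patterns sit around 0.2-0.4 from
the clean clusters, and unrelated templates sit near sqrt(2) and beyond,
so a cut inside the first gap separates clean pattern clusters from both
hybrids and scatter, and the cluster count emerges from the data.
(Silhouette-based cluster-count selection fails here: with
many scattered non-pattern candidates, the tight clusters of two distinct
patterns are mutually closer than the scatter and get merged at any capped
k. The mean silhouette of the chosen partition is still reported.)

A cluster is *robust* when (i) it holds at least 5% of all candidates,
(ii) its members account for at least 5% of all occurrences, and (iii) more
than half of its members each occur in at least 80% (short windows) or 50%
(long windows) of subjects. The representative QPP (rQPP) of a robust
cluster is the member with the highest total correlation with the image
series, summed across its occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .io_types import ImageSeries, frames_to_subjects
from .qpp_extract import QPP

__all__ = ["ClusterReport", "qpp_distance", "cluster_qpps", "phase_align"]

SIZE_FRACTION_MIN = 0.05
OCCURRENCE_FRACTION_MIN = 0.05
SUBJECT_COVERAGE = {"short": 0.8, "long": 0.5}


@dataclass
class ClusterReport:
    """Outcome of clustering one window-size's candidate pool."""

    distance_matrix: np.ndarray  # (n, n) over clustered candidates
    candidate_indices: np.ndarray  # indices into the input list (converged only)
    labels: np.ndarray  # cluster id per input candidate; -1 = excluded
    robust: set[int]
    representative: dict[int, int]  # robust cluster id -> input-candidate index
    criteria_log: dict[int, dict[str, float]]
    n_clusters: int = 0
    silhouette: float = float("nan")

    def representative_qpps(self, candidates: list[QPP]) -> dict[int, QPP]:
        return {cid: candidates[i] for cid, i in self.representative.items()}


def _shifted_template_corr(a: np.ndarray, b: np.ndarray, max_shift: int) -> tuple[float, int]:
    """Best flattened-template Pearson over circular window shifts of ``b``.

    Ties prefer the smallest |shift|, then negative before positive.
    """
    best_r, best_s = -np.inf, 0
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)):
        r = _corr(a.ravel(), np.roll(b, s, axis=1).ravel())
        if r > best_r + 1e-15:
            best_r, best_s = r, s
    return best_r, best_s


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def _shifted_stc_corr(a: np.ndarray, b: np.ndarray, max_shift: int) -> float:
    """Best STC-trace correlation over small relative frame shifts.

    Two candidates that found the same pattern at a 1-frame phase offset
    (the typical phase indeterminacy of the iteration) have sharply peaked
    STC traces that decorrelate at lag 0; aligning over the same small
    shift range used for templates restores the match.
    """
    best = -np.inf
    L = len(a)
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            r = _corr(a[s:], b[: L - s]) if L - s > 1 else -1.0
        else:
            r = _corr(a[: L + s], b[-s:]) if L + s > 1 else -1.0
        best = max(best, r)
    return best


def qpp_distance(a: QPP, b: QPP, max_shift: int = 2) -> tuple[float, float, float]:
    """Spatial, temporal and combined distance between two QPPs.

    spatial = 1 - max-over-circular-window-shifts template correlation;
    temporal = 1 - max-over-frame-shifts STC correlation (same +/-max_shift
    range); combined = their Euclidean norm.
    """
    if a.window != b.window:
        raise ValueError("QPPs have different windows")
    if a.template.shape != b.template.shape:
        raise ValueError("QPPs have different voxel counts")
    r_spat, _ = _shifted_template_corr(a.template, b.template, max_shift)
    spatial = 1.0 - r_spat
    temporal = 1.0 - _shifted_stc_corr(a.stc, b.stc, max_shift)
    return spatial, temporal, float(np.hypot(spatial, temporal))


def phase_align(a: QPP, b: QPP, max_shift: int = 2) -> int:
    """Circular window shift to apply to ``b`` so it best matches ``a``.

    If ``b`` equals ``a`` shifted by +1 frame, the returned shift is -1.
    Ties break to the smallest |shift|, negative before positive.
    """
    if a.window != b.window:
        raise ValueError("QPPs have different windows")
    _, s = _shifted_template_corr(a.template, b.template, max_shift)
    return s


def _subject_coverage(qpp: QPP, series: ImageSeries) -> float:
    """Fraction of subjects in which this QPP occurs at least once."""
    if len(qpp.occurrences) == 0:
        return 0.0
    subs = set(frames_to_subjects(series, qpp.occurrences))
    return len(subs) / len(series.subjects)


def cluster_qpps(
    candidates: list[QPP],
    series: ImageSeries,
    window_kind: str,
    cut_distance: float = 0.3,
    max_shift: int = 2,
) -> ClusterReport:
    """Cluster candidates, apply the robustness criteria, pick representatives.

    ``window_kind`` is "short" or "long"; it selects the subject-coverage
    bound (80% vs 50%). Non-converged candidates are excluded from
    clustering (label -1) but still count in the 5%-of-candidates
    denominator. An empty robust set is a valid outcome and is reported as
    such.
    """
    if window_kind not in SUBJECT_COVERAGE:
        raise ValueError("window_kind must be 'short' or 'long'")
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to cluster")
    keep = np.array([i for i, q in enumerate(candidates) if q.converged], dtype=int)
    if len(keep) < 2:
        # fewer than two recurring patterns found at all: report the empty
        # outcome rather than erroring (mirrors the no-robust-cluster case)
        return ClusterReport(
            distance_matrix=np.zeros((0, 0)),
            candidate_indices=keep,
            labels=np.full(len(candidates), -1, dtype=int),
            robust=set(),
            representative={},
            criteria_log={},
            n_clusters=0,
            silhouette=float("nan"),
        )
    pool = [candidates[i] for i in keep]
    n = len(pool)

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, d = qpp_distance(pool[i], pool[j], max_shift=max_shift)
            dist[i, j] = dist[j, i] = d

    Z = linkage(squareform(dist, checks=False), method="average")
    pool_labels = fcluster(Z, t=cut_distance, criterion="distance")
    k = len(np.unique(pool_labels))
    if 2 <= k <= n - 1:
        sil = float(silhouette_score(dist, pool_labels, metric="precomputed"))
    else:
        sil = float("nan")

    labels = np.full(len(candidates), -1, dtype=int)
    labels[keep] = pool_labels

    total_candidates = len(candidates)
    total_occurrences = sum(q.n_occurrences for q in pool)
    coverage_bound = SUBJECT_COVERAGE[window_kind]

    robust: set[int] = set()
    representative: dict[int, int] = {}
    criteria_log: dict[int, dict[str, float]] = {}
    for cid in sorted(set(pool_labels)):
        members = keep[pool_labels == cid]
        size_frac = len(members) / total_candidates
        occ_frac = (
            sum(candidates[i].n_occurrences for i in members) / total_occurrences
            if total_occurrences
            else 0.0
        )
        cov_ok = [
            _subject_coverage(candidates[i], series) >= coverage_bound for i in members
        ]
        cov_frac = float(np.mean(cov_ok))
        criteria_log[int(cid)] = {
            "size_fraction": size_frac,
            "occurrence_fraction": occ_frac,
            "subject_coverage_fraction": cov_frac,
        }
        if (
            size_frac >= SIZE_FRACTION_MIN
            and occ_frac >= OCCURRENCE_FRACTION_MIN
            and cov_frac > 0.5
        ):
            robust.add(int(cid))
            strengths = [candidates[i].occurrence_strength() for i in members]
            representative[int(cid)] = int(members[int(np.argmax(strengths))])

    return ClusterReport(
        distance_matrix=dist,
        candidate_indices=keep,
        labels=labels,
        robust=robust,
        representative=representative,
        criteria_log=criteria_log,
        n_clusters=int(k),
        silhouette=sil,
    )
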