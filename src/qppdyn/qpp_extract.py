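"""Quasi-periodic pattern (QPP) extraction by iterative sliding-template
correlation.

The algorithm: take the image-series segment at a random starting frame as
an initial voxel x window template; correlate it with every same-length
segment of the series stepped by one frame (the sliding template
correlation, STC); average the series over the windows starting at
supra-threshold local maxima of the STC to form an updated template; repeat
until consecutive templates correlate above 0.99. The whole procedure is
reiterated from many random starting frames (200 in the reference
protocol), yielding a pool of candidate QPPs for clustering.

Windows that would cross a subject boundary in the concatenated group
series are excluded: their STC entries are fixed at 0 and they can never be
occurrences. Zero-variance windows also correlate as 0 (Pearson undefined;
0 is neutral and excludes them from maxima).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_types import ImageSeries

__all__ = [
    "QPP",
    "compute_stc",
    "find_occurrences",
    "refine_template",
    "extract_candidates",
    "valid_start_frames",
]

DEFAULT_THRESHOLD = 0.2
RAMP_THRESHOLD = 0.1
RAMP_ITERATIONS = 3
DEFAULT_CONVERGENCE = 0.99
DEFAULT_MAX_ITER = 20
DEFAULT_N_STARTS = 200


@dataclass
class QPP:
    """A spatiotemporal template with its STC trace and occurrences.

    ``occurrences`` are window START frames (0-based) of supra-threshold
    local maxima of ``stc``; each window lies wholly inside one subject
    segment. After convergence the template equals the voxel-wise mean of
    the series over the occurrence windows.
    """

    template: np.ndarray  # (V, W)
    window: int
    stc: np.ndarray  # (T - W + 1,)
    occurrences: np.ndarray  # start frames, int
    threshold: float = DEFAULT_THRESHOLD
    n_iterations: int = 0
    seed_frame: int = -1
    converged: bool = False

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=np.float64)
        self.stc = np.asarray(self.stc, dtype=np.float64)
        self.occurrences = np.asarray(self.occurrences, dtype=np.int64)

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)

    def occurrence_strength(self) -> float:
        """Total correlation with the series, summed across occurrences."""
        return float(self.stc[self.occurrences].sum()) if len(self.occurrences) else 0.0


class _SeriesCache:
    """Per-series precomputations reused across many STC evaluations."""

    def __init__(self, series: ImageSeries, window: int):
        data = series.data
        V, T = data.shape
        if window > min(n for _, _, n in series.subjects):
            raise ValueError("window longer than the shortest subject segment")
        self.window = window
        self.n_starts = T - window + 1
        csum = np.concatenate([[0.0], np.cumsum(data.sum(axis=0))])
        csq = np.concatenate([[0.0], np.cumsum((data * data).sum(axis=0))])
        idx = np.arange(self.n_starts)
        self.win_sum = csum[idx + window] - csum[idx]  # sum of x over each window
        self.win_sq = csq[idx + window] - csq[idx]  # sum of x^2 over each window
        valid = np.zeros(self.n_starts, dtype=bool)
        for _, start, n in series.subjects:
            hi = start + n - window
            if hi >= start:
                valid[start : hi + 1] = True
        self.valid = valid
        self.valid_starts = np.flatnonzero(valid)
        self.n = float(V * window)


def valid_start_frames(series: ImageSeries, window: int) -> np.ndarray:
    """Start frames whose window fits wholly inside one subject segment."""
    return _SeriesCache(series, window).valid_starts


def compute_stc(
    series: ImageSeries, template: np.ndarray, _cache: _SeriesCache | None = None
) -> np.ndarray:
    """Pearson correlation of the template with every valid series segment.

    ``stc[t]`` correlates the flattened template with the flattened segment
    ``[t, t + W)``. Starts whose window crosses a subject boundary, and
    zero-variance segments/templates, yield 0.
    """
    template = np.asarray(template, dtype=np.float64)
    if template.ndim != 2 or template.shape[0] != series.n_voxels:
        raise ValueError(
            f"template shape {template.shape} incompatible with V={series.n_voxels}"
        )
    W = template.shape[1]
    cache = _cache if _cache is not None else _SeriesCache(series, W)
    if cache.window != W:
        raise ValueError("cache built for a different window")
    data = series.data
    L = cache.n_starts
    n = cache.n

    # cross term: D[t] = sum_w template[:, w] . data[:, t + w]
    M = template.T @ data  # (W, T)
    D = np.zeros(L)
    for w in range(W):
        D += M[w, w : w + L]

    sy = template.sum()
    syy = (template * template).sum()
    var_y = syy - sy * sy / n
    stc = np.zeros(L)
    if var_y > 1e-12:
        var_x = cache.win_sq - cache.win_sum**2 / n
        cov = D - cache.win_sum * sy / n
        ok = cache.valid & (var_x > 1e-12)
        stc[ok] = cov[ok] / np.sqrt(var_x[ok] * var_y)
        np.clip(stc, -1.0, 1.0, out=stc)
    return stc


def find_occurrences(
    stc: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    series: ImageSeries | None = None,
    window: int | None = None,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Supra-threshold strict local maxima of the STC (window start frames).

    Within each run of consecutive valid starts, a plateau of equal values
    is a maximum iff it exceeds the threshold and both plateau-exterior
    neighbours (a run endpoint needs only its single interior neighbour to
    be strictly below); the first frame of the plateau is returned.
    """
    stc = np.asarray(stc, dtype=np.float64)
    if valid is None:
        if series is not None and window is not None:
            cache = _SeriesCache(series, window)
            if cache.n_starts != len(stc):
                raise ValueError("stc length does not match series/window")
            valid = cache.valid
        else:
            valid = np.ones(len(stc), dtype=bool)
    occ: list[int] = []
    L = len(stc)
    i = 0
    while i < L:
        if not valid[i]:
            i += 1
            continue
        j = i  # run of valid starts [i, j]
        while j + 1 < L and valid[j + 1]:
            j += 1
        k = i
        while k <= j:
            m = k  # plateau [k, m]
            while m < j and stc[m + 1] == stc[k]:
                m += 1
            v = stc[k]
            left_ok = k == i or stc[k - 1] < v
            right_ok = m == j or stc[m + 1] < v
            if v > threshold and left_ok and right_ok:
                occ.append(k)
            k = m + 1
        i = j + 1
    return np.array(occ, dtype=np.int64)


def _mean_over_windows(data: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    acc = np.zeros((data.shape[0], window))
    for s in starts:
        acc += data[:, s : s + window]
    return acc / len(starts)


def _flat_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def refine_template(
    series: ImageSeries,
    seed_frame: int,
    window: int,
    threshold: float = DEFAULT_THRESHOLD,
    convergence: float = DEFAULT_CONVERGENCE,
    max_iter: int = DEFAULT_MAX_ITER,
    ramp_threshold: float = RAMP_THRESHOLD,
    ramp_iterations: int = RAMP_ITERATIONS,
    _cache: _SeriesCache | None = None,
) -> QPP:
    """Iterate template <-> occurrences from one seed frame until convergence.

    The first ``ramp_iterations`` iterations gather occurrences at the lower
    ``ramp_threshold`` before tightening to ``threshold`` — the standard
    ramp that lets a start whose seed window only partially overlaps a
    pattern collect enough instances to converge onto it; without it, only
    seeds essentially inside an occurrence ever find the pattern. The final
    STC and occurrence list are always computed at the full ``threshold``.
    Set ``ramp_iterations=0`` for a fixed threshold throughout.

    Convergence: correlation between flattened consecutive templates
    > ``convergence``, with at least 2 final occurrences — a template whose
    only occurrence is its own seed window is a fixed point of the
    iteration but not a recurring pattern, so it is flagged non-converged.
    Non-convergence (iteration cap hit, or occurrences vanish) is flagged,
    not fatal. The final STC and occurrences are always recomputed from the
    final template.
    """
    cache = _cache if _cache is not None else _SeriesCache(series, window)
    if not (0 <= seed_frame < cache.n_starts and cache.valid[seed_frame]):
        raise ValueError(f"seed frame {seed_frame} is not a valid window start")
    template = series.data[:, seed_frame : seed_frame + window].copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        thr = ramp_threshold if n_iter <= ramp_iterations else threshold
        stc = compute_stc(series, template, _cache=cache)
        occ = find_occurrences(stc, thr, valid=cache.valid)
        if len(occ) == 0:
            return QPP(
                template=template, window=window, stc=stc,
                occurrences=occ, threshold=threshold, n_iterations=n_iter,
                seed_frame=seed_frame, converged=False,
            )
        new_template = _mean_over_windows(series.data, occ, window)
        if _flat_corr(template, new_template) > convergence:
            template = new_template
            converged = True
            break
        template = new_template
    stc = compute_stc(series, template, _cache=cache)
    occ = find_occurrences(stc, threshold, valid=cache.valid)
    return QPP(
        template=template, window=window, stc=stc, occurrences=occ,
        threshold=threshold, n_iterations=n_iter, seed_frame=seed_frame,
        converged=converged and len(occ) >= 2,
    )


def extract_candidates(
    series: ImageSeries,
    window: int,
    n_starts: int = DEFAULT_N_STARTS,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    convergence: float = DEFAULT_CONVERGENCE,
    max_iter: int = DEFAULT_MAX_ITER,
    ramp_threshold: float = RAMP_THRESHOLD,
    ramp_iterations: int = RAMP_ITERATIONS,
) -> list[QPP]:
    """Run the refinement from ``n_starts`` random starting frames.

    Seed frames are drawn uniformly without replacement from the valid
    starts using the given seed; every start yields a QPP (non-converged
    ones are flagged, not dropped).
    """
    cache = _SeriesCache(series, window)
    starts = cache.valid_starts
    if n_starts > len(starts):
        raise ValueError(f"{n_starts} starts requested but only {len(starts)} valid")
    rng = np.random.Generator(np.random.PCG64(seed))
    seeds = np.sort(rng.choice(starts, size=n_starts, replace=False))
    return [
        refine_template(
            series, int(s), window, threshold=threshold,
            convergence=convergence, max_iter=max_iter,
            ramp_threshold=ramp_threshold, ramp_iterations=ramp_iterations,
            _cache=cache,
        )
        for s in seeds
    ]
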