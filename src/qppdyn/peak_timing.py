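"""Null-model voxel significance and regional peak-timing analysis of long
QPPs.

To decide which voxels genuinely participate in a long pattern, an ensemble
of 50 *null* templates is built: each averages randomly chosen,
non-overlapping series segments that avoid the pattern's real occurrence
windows, with the per-subject segment count matched to that subject's
occurrence count. The root-sum-square (RSS) of each voxel's template time
course is the effect size; voxels whose real RSS exceeds the 95th
percentile of the pooled null RSS values are significant.

Significant voxels are assigned to named atlas regions. Within every
occurrence window each voxel shows two peaks of absolute BOLD value — one in
the first half of the window, one in the second — whose frames are averaged
across occurrences into per-voxel peak timings. Three tiers of comparisons
follow: (1) per-region mean timing between groups, (2) region-pair timing
differences within a group, and (3) region-pair timing *intervals* between
groups, where the unequal voxel counts of a pair are handled by differencing
each voxel of the smaller region against the mean timing of the bigger one.
All tiers use two-sample t-tests with Benjamini-Hochberg FDR across the two
peaks and all regions (or region pairs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_types import Atlas, ImageSeries
from .qpp_extract import QPP

__all__ = [
    "NullEnsemble",
    "TimingResult",
    "build_null_ensemble",
    "rss",
    "significant_voxels",
    "extract_peak_timings",
    "compare_timings",
]

DEFAULT_N_NULL = 50
RSS_PERCENTILE = 95.0
MAX_ATTEMPTS = 10_000


@dataclass
class NullEnsemble:
    """Occurrence-avoiding null templates for RSS calibration."""

    n_null: int
    null_templates: list[np.ndarray]  # each (V, W)
    segment_starts: list[np.ndarray]  # start frames used by each null
    rng_seed: int


def build_null_ensemble(
    series: ImageSeries, qpp: QPP, n_null: int = DEFAULT_N_NULL, seed: int = 0
) -> NullEnsemble:
    """Draw ``n_null`` null templates from occurrence-free stretches.

    Within each subject, the number of random segments equals that
    subject's occurrence count; segments may not overlap each other nor any
    real occurrence window. Rejection sampling is capped at
    ``MAX_ATTEMPTS`` draws per ensemble; hitting the cap raises a capacity
    error with per-subject diagnostics.
    """
    W = qpp.window
    occ = np.asarray(qpp.occurrences, dtype=np.int64)
    if occ.size == 0:
        raise ValueError("QPP has no occurrences; null ensemble undefined")
    # per-subject quotas and forbidden frames
    quotas: dict[str, int] = {}
    for sid, start, n in series.subjects:
        quotas[sid] = int(np.sum((occ >= start) & (occ < start + n)))
    rng = np.random.Generator(np.random.PCG64(seed))
    occupied_base = np.zeros(series.n_frames, dtype=bool)
    for o in occ:
        occupied_base[o : o + W] = True

    templates: list[np.ndarray] = []
    all_starts: list[np.ndarray] = []
    for _ in range(n_null):
        occupied = occupied_base.copy()
        starts: list[int] = []
        attempts = 0
        for sid, s0, n in series.subjects:
            need = quotas[sid]
            got = 0
            hi = s0 + n - W
            while got < need:
                attempts += 1
                if attempts > MAX_ATTEMPTS:
                    raise RuntimeError(
                        "null-segment sampling exhausted "
                        f"({MAX_ATTEMPTS} attempts); subject {sid} needed "
                        f"{need} segments, placed {got} "
                        f"(occurrence-free frames may be too scarce)"
                    )
                cand = int(rng.integers(s0, hi + 1))
                if not occupied[cand : cand + W].any():
                    occupied[cand : cand + W] = True
                    starts.append(cand)
                    got += 1
        starts_arr = np.array(sorted(starts), dtype=np.int64)
        tpl = np.zeros((series.n_voxels, W))
        for s in starts_arr:
            tpl += series.data[:, s : s + W]
        tpl /= len(starts_arr)
        templates.append(tpl)
        all_starts.append(starts_arr)
    return NullEnsemble(
        n_null=n_null, null_templates=templates, segment_starts=all_starts, rng_seed=seed
    )


def rss(template: np.ndarray) -> np.ndarray:
    """Root sum square of each voxel's values across the window frames."""
    template = np.asarray(template, dtype=np.float64)
    return np.sqrt((template * template).sum(axis=1))


def significant_voxels(
    qpp: QPP,
    nulls: NullEnsemble,
    atlas: Atlas,
    regions: list[str],
    series: ImageSeries,
    percentile: float = RSS_PERCENTILE,
    per_voxel: bool = False,
) -> pd.DataFrame:
    """Voxels whose RSS beats the null's 95th percentile, labeled by region.

    The percentile is taken over the pooled (n_null x V) null RSS values by
    default (``per_voxel=True`` switches to a per-voxel null distribution).
    Significant voxels outside the named regions are dropped from timing
    analysis. Returns a DataFrame with columns ``voxel`` and ``region``.
    """
    real = rss(qpp.template)
    null_rss = np.stack([rss(t) for t in nulls.null_templates])  # (n_null, V)
    if per_voxel:
        thr = np.percentile(null_rss, percentile, axis=0)
    else:
        thr = np.percentile(null_rss.ravel(), percentile)
    sig = np.flatnonzero(real > thr)
    labels = atlas.labels[tuple(series.voxel_coords[sig].T)]
    name_of = {atlas.label_of(r): r for r in regions}
    rows = [
        (int(v), name_of[lab]) for v, lab in zip(sig, labels) if lab in name_of
    ]
    df = pd.DataFrame(rows, columns=["voxel", "region"])
    df.attrs["n_significant_total"] = int(len(sig))
    df.attrs["threshold"] = float(np.mean(thr))
    return df


def extract_peak_timings(
    series: ImageSeries, qpp: QPP, voxels: pd.DataFrame
) -> pd.DataFrame:
    """Mean first/second-half |BOLD| peak frames per significant voxel.

    For every occurrence window and voxel, peak 1 is the argmax of the
    absolute signal over frames [0, W/2) and peak 2 over [W/2, W); ties
    break to the earliest frame. Timings are averaged across occurrences and
    reported in frames (seconds = frames x TR).
    """
    W = qpp.window
    if W % 2:
        raise ValueError("peak timing needs an even window")
    half = W // 2
    occ = np.asarray(qpp.occurrences, dtype=np.int64)
    if occ.size == 0:
        raise ValueError("QPP has no occurrences")
    vox = voxels["voxel"].to_numpy(dtype=int)
    p1 = np.zeros((len(vox), len(occ)))
    p2 = np.zeros((len(vox), len(occ)))
    for k, s in enumerate(occ):
        seg = np.abs(series.data[np.ix_(vox, np.arange(s, s + W))])
        p1[:, k] = np.argmax(seg[:, :half], axis=1)
        p2[:, k] = half + np.argmax(seg[:, half:], axis=1)
    out = voxels.copy()
    out["peak1"] = p1.mean(axis=1)
    out["peak2"] = p2.mean(axis=1)
    out["peak1_seconds"] = out["peak1"] * series.tr_seconds
    out["peak2_seconds"] = out["peak2"] * series.tr_seconds
    return out


@dataclass
class TimingResult:
    """Three tiers of peak-timing comparisons between two groups."""

    timings_A: pd.DataFrame
    timings_B: pd.DataFrame
    tier1: pd.DataFrame  # per-region group comparison
    tier2: pd.DataFrame  # within-group region-pair comparison
    tier3: pd.DataFrame  # between-group region-pair interval comparison
    excluded_regions: list[str] = field(default_factory=list)


def _t_pooled(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def _fdr(df: pd.DataFrame) -> pd.DataFrame:
    if len(df):
        ok = np.isfinite(df["p_raw"].to_numpy())
        p_fdr = np.full(len(df), np.nan)
        if ok.any():
            p_fdr[ok] = multipletests(df["p_raw"].to_numpy()[ok], method="fdr_bh")[1]
        df = df.assign(p_fdr=p_fdr, significant=p_fdr < 0.05)
    else:
        df = df.assign(p_fdr=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    return df


def compare_timings(
    timings_A: pd.DataFrame,
    timings_B: pd.DataFrame,
    regions: list[str] | None = None,
    min_voxels: int = 2,
) -> TimingResult:
    """Run the three timing-comparison tiers with joint FDR per tier.

    Group B's timings are expected to come from the PROJECTED occurrences of
    group A's representative QPP, so both groups describe the same pattern.
    Regions with fewer than ``min_voxels`` significant voxels in either
    group are excluded and logged.
    """
    if regions is None:
        regions = sorted(set(timings_A["region"]) | set(timings_B["region"]))
    counts_a = timings_A["region"].value_counts()
    counts_b = timings_B["region"].value_counts()
    usable = [
        r for r in regions
        if counts_a.get(r, 0) >= min_voxels and counts_b.get(r, 0) >= min_voxels
    ]
    excluded = [r for r in regions if r not in usable]

    def region_vals(df: pd.DataFrame, region: str, peak: str) -> np.ndarray:
        return df.loc[df["region"] == region, peak].to_numpy()

    # tier 1: per region, per peak, group A vs group B voxel timings
    rows = []
    for region in usable:
        for peak in ("peak1", "peak2"):
            a = region_vals(timings_A, region, peak)
            b = region_vals(timings_B, region, peak)
            t, p = _t_pooled(a, b)
            rows.append(
                dict(region=region, peak=peak, mean_A=a.mean(), mean_B=b.mean(),
                     t=t, p_raw=p)
            )
    tier1 = _fdr(pd.DataFrame(rows))

    # tier 2: within each group, per region pair, per peak
    rows = []
    for group, df in (("A", timings_A), ("B", timings_B)):
        for r1, r2 in itertools.combinations(usable, 2):
            for peak in ("peak1", "peak2"):
                a = region_vals(df, r1, peak)
                b = region_vals(df, r2, peak)
                t, p = _t_pooled(a, b)
                rows.append(
                    dict(group=group, region_1=r1, region_2=r2, peak=peak,
                         mean_1=a.mean(), mean_2=b.mean(), t=t, p_raw=p)
                )
    tier2 = pd.DataFrame(rows)
    # FDR within each group's family (2 peaks x pairs)
    parts = []
    for group in ("A", "B"):
        parts.append(_fdr(tier2[tier2["group"] == group].copy()))
    tier2 = pd.concat(parts, ignore_index=True) if parts else tier2

    # tier 3: between-group comparison of region-pair timing intervals,
    # each voxel of the smaller region differenced against the mean of the
    # bigger region (within its own group)
    def intervals(df: pd.DataFrame, r1: str, r2: str, peak: str) -> np.ndarray:
        a = region_vals(df, r1, peak)
        b = region_vals(df, r2, peak)
        if len(a) <= len(b):
            return a - b.mean()
        return a.mean() - b

    rows = []
    for r1, r2 in itertools.combinations(usable, 2):
        for peak in ("peak1", "peak2"):
            da = intervals(timings_A, r1, r2, peak)
            db = intervals(timings_B, r1, r2, peak)
            t, p = _t_pooled(da, db)
            rows.append(
                dict(region_1=r1, region_2=r2, peak=peak,
                     mean_interval_A=da.mean(), mean_interval_B=db.mean(),
                     t=t, p_raw=p)
            )
    tier3 = _fdr(pd.DataFrame(rows))

    return TimingResult(
        timings_A=timings_A, timings_B=timings_B,
        tier1=tier1, tier2=tier2, tier3=tier3,
        excluded_regions=excluded,
    )
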