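"""Voxel-wise T maps, static functional connectivity, and occurrence-rate
group tests.

T maps summarise a QPP's (de)activation: a one-sample t-test per voxel and
window frame of the BOLD values across occurrence windows, or a two-sample
test between two groups' occurrence stacks. Maps are thresholded by
Benjamini-Hochberg FDR (q = 0.05) followed by a spatial cluster-extent
filter (6-connected components of at least k = 10 voxels at a single
frame).

Static FC is the classic ROI-pair measure: Pearson correlation between
region-averaged time series per subject, Fisher z-transformed. Occurrence
rates between groups are compared by two-sample t-tests with FDR across the
family of patterns tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .io_types import Atlas, ImageSeries
from .qpp_extract import QPP

__all__ = [
    "StatMap",
    "FCMatrix",
    "one_sample_tmap",
    "two_sample_tmap",
    "fc_matrix",
    "compare_rates",
    "bh_fdr",
    "cluster_extent_filter",
    "occurrence_stack",
]

FDR_Q = 0.05
CLUSTER_K = 10


@dataclass
class StatMap:
    """Voxel(-by-frame) t statistics with FDR and extent-filtered mask."""

    t: np.ndarray  # (V,) or (V, W)
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray  # bool, same shape
    degenerate: np.ndarray  # zero-variance voxels flagged
    df: float


@dataclass
class FCMatrix:
    """Per-subject Fisher-z ROI connectivity (diagonal NaN)."""

    z: np.ndarray  # (R, R)
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.shape != (len(self.roi_names),) * 2:
            raise ValueError("z must be R x R")


def bh_fdr(p: np.ndarray, q: float = FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg: (reject mask, adjusted p-values)."""
    p = np.asarray(p, dtype=np.float64)
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape), p_adj.reshape(p.shape)


def cluster_extent_filter(
    volume: np.ndarray, k: int = CLUSTER_K
) -> np.ndarray:
    """Keep only 6-connected components of at least ``k`` voxels."""
    labeled, n = ndimage.label(volume)  # default structure = 6-connectivity
    if n == 0:
        return np.zeros_like(volume, dtype=bool)
    sizes = np.bincount(labeled.ravel())
    keep = np.flatnonzero(sizes >= k)
    keep = keep[keep != 0]
    return np.isin(labeled, keep)


def _extent_filter_frames(
    sig: np.ndarray, series: ImageSeries, k: int
) -> np.ndarray:
    """Apply the spatial extent filter to each frame of a (V,) or (V, F) mask."""
    sig2 = sig[:, np.newaxis] if sig.ndim == 1 else sig
    out = np.zeros_like(sig2)
    for f in range(sig2.shape[1]):
        vol = series.to_volume(sig2[:, f])
        out[:, f] = cluster_extent_filter(vol, k)[tuple(series.voxel_coords.T)]
    return out[:, 0] if sig.ndim == 1 else out


def occurrence_stack(series: ImageSeries, qpp: QPP) -> np.ndarray:
    """BOLD values across occurrence windows: (n_occ, V, W)."""
    occ = np.asarray(qpp.occurrences, dtype=np.int64)
    if occ.size == 0:
        raise ValueError("QPP has no occurrences")
    W = qpp.window
    return np.stack([series.data[:, s : s + W] for s in occ])


def _finish_map(
    t: np.ndarray, p: np.ndarray, degenerate: np.ndarray,
    series: ImageSeries, q: float, k: int, df: float,
) -> StatMap:
    p = p.copy()
    p[degenerate] = 0.0  # infinite t treated as certain activation, flagged
    _, p_fdr = bh_fdr(p, q)
    sig = p_fdr < q
    sig = _extent_filter_frames(sig, series, k)
    return StatMap(t=t, p_raw=p, p_fdr=p_fdr, significant=sig,
                   degenerate=degenerate, df=df)


def one_sample_tmap(
    qpp: QPP,
    series: ImageSeries,
    collapse_window: bool = False,
    q: float = FDR_Q,
    k: int = CLUSTER_K,
) -> StatMap:
    """One-sample t map of BOLD across a QPP's occurrences, per window frame.

    ``collapse_window=True`` averages each occurrence window over frames
    first, giving a single (V,) map. FDR is applied over all voxels x frames
    of the map; the extent filter runs spatially at each frame.
    """
    stack = occurrence_stack(series, qpp)  # (n, V, W)
    if collapse_window:
        stack = stack.mean(axis=2)  # (n, V)
    n = stack.shape[0]
    if n < 2:
        raise ValueError("need >= 2 occurrences")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    degenerate = sd <= 1e-300
    t = np.where(degenerate, np.sign(mean) * np.inf, mean * np.sqrt(n) / np.where(degenerate, 1.0, sd))
    p = 2.0 * stats.t.sf(np.abs(np.where(degenerate, 0.0, t)), df=n - 1)
    return _finish_map(t, p, degenerate, series, q, k, df=n - 1)


def two_sample_tmap(
    a: np.ndarray,
    b: np.ndarray,
    series: ImageSeries,
    q: float = FDR_Q,
    k: int = CLUSTER_K,
) -> StatMap:
    """Pooled-variance two-sample t map between two occurrence stacks.

    ``a`` and ``b`` are (n, V) or (n, V, W) stacks on the same voxel grid.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("stacks must share voxel/window shape")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group")
    res = stats.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(res.statistic)
    p = np.asarray(res.pvalue)
    degenerate = ~np.isfinite(t)
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
    return _finish_map(t, p, degenerate, series, q, k, df=na + nb - 2)


def fc_matrix(
    series: ImageSeries, atlas: Atlas, rois: list[str]
) -> list[FCMatrix]:
    """Per-subject ROI x ROI Fisher-z connectivity matrices.

    Region time series are the mean over each ROI's mask voxels within the
    subject's segment; z = atanh(Pearson r) per pair.
    """
    idx = {}
    for roi in rois:
        vox = atlas.region_voxel_indices(series, roi)
        if len(vox) == 0:
            raise ValueError(f"ROI {roi!r} has no voxels inside the mask")
        idx[roi] = vox
    out = []
    for sid, start, n in series.subjects:
        seg = series.data[:, start : start + n]
        ts = np.stack([seg[idx[roi]].mean(axis=0) for roi in rois])
        r = np.corrcoef(ts)
        np.fill_diagonal(r, np.nan)
        with np.errstate(divide="ignore"):
            z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        np.fill_diagonal(z, np.nan)
        out.append(FCMatrix(z=z, roi_names=list(rois)))
    return out


def compare_rates(
    rates_A: dict[str, np.ndarray] | pd.DataFrame,
    rates_B: dict[str, np.ndarray] | pd.DataFrame,
    q: float = FDR_Q,
) -> pd.DataFrame:
    """Two-sample t-test of per-subject occurrence rates, FDR over patterns.

    ``rates_A`` / ``rates_B`` map pattern name -> per-subject rates (/min).
    The family for FDR is the set of patterns tested together.
    """
    if isinstance(rates_A, pd.DataFrame):
        rates_A = {c: rates_A[c].to_numpy() for c in rates_A.columns}
    if isinstance(rates_B, pd.DataFrame):
        rates_B = {c: rates_B[c].to_numpy() for c in rates_B.columns}
    if set(rates_A) != set(rates_B):
        raise ValueError("pattern families differ between groups")
    rows = []
    for name in rates_A:
        a = np.asarray(rates_A[name], dtype=np.float64)
        b = np.asarray(rates_B[name], dtype=np.float64)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 subjects per group")
        res = stats.ttest_ind(a, b, equal_var=True)
        p = float(res.pvalue)
        if not np.isfinite(p):  # identical constant vectors
            p = 1.0
        rows.append(
            dict(pattern=name, mean_A=a.mean(), sd_A=a.std(ddof=1),
                 mean_B=b.mean(), sd_B=b.std(ddof=1),
                 t=float(res.statistic) if np.isfinite(res.statistic) else 0.0,
                 p_raw=p)
        )
    df = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(df["p_raw"].to_numpy(), q)
    df["p_fdr"] = p_adj
    df["significant"] = reject
    return df
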