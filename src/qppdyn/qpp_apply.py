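"""Applying a representative QPP to an image series: cross-group projection,
occurrence rates, and regression of the pattern out of the series.

Projection correlates one group's rQPP template with another group's series
(the same sliding-template correlation used in extraction), takes the
supra-threshold local maxima as projected occurrences, and averages the
target series over those windows to get the projected pattern. Occurrence
rates are counts per minute of scan time, per subject and pooled.

QPP regression removes a pattern's contribution from the BOLD signal: the
template is convolved with its own STC trace to build a per-voxel regressor
(the "QPP image series"), and each voxel is replaced by the residual of a
least-squares fit on [intercept, regressor]. FC computed on the residuals
then reflects connectivity without that QPP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .io_types import ImageSeries, frames_to_subjects
from .qpp_extract import QPP, _SeriesCache, compute_stc, find_occurrences

__all__ = ["Projection", "project", "occurrence_rate", "regress_qpp"]


@dataclass
class Projection:
    """One QPP evaluated on a (possibly different) image series."""

    source_qpp: QPP
    target_stc: np.ndarray
    target_occurrences: np.ndarray
    projected_pattern: np.ndarray | None  # (V, W); None when no occurrences
    per_subject_rates: dict[str, float]
    pooled_rate: float


def occurrence_rate(
    occurrences: np.ndarray, series: ImageSeries
) -> tuple[dict[str, float], float]:
    """Occurrences per minute, per subject and pooled over the whole series."""
    occurrences = np.asarray(occurrences, dtype=np.int64)
    if occurrences.size:
        subs = frames_to_subjects(series, occurrences)
    else:
        subs = np.array([], dtype=object)
    rates: dict[str, float] = {}
    for sid, _, n in series.subjects:
        minutes = n * series.tr_seconds / 60.0
        rates[sid] = float(np.sum(subs == sid)) / minutes
    total_minutes = series.n_frames * series.tr_seconds / 60.0
    return rates, len(occurrences) / total_minutes


def project(qpp: QPP, target: ImageSeries, threshold: float = 0.2) -> Projection:
    """Project a QPP onto a target series: STC, occurrences, pattern, rates."""
    if qpp.template.shape[0] != target.n_voxels:
        raise ValueError(
            f"QPP has {qpp.template.shape[0]} voxels, series has {target.n_voxels}"
        )
    cache = _SeriesCache(target, qpp.window)
    stc = compute_stc(target, qpp.template, _cache=cache)
    occ = find_occurrences(stc, threshold, valid=cache.valid)
    if len(occ):
        pattern = np.zeros((target.n_voxels, qpp.window))
        for s in occ:
            pattern += target.data[:, s : s + qpp.window]
        pattern /= len(occ)
    else:
        pattern = None
    rates, pooled = occurrence_rate(occ, target)
    return Projection(
        source_qpp=qpp,
        target_stc=stc,
        target_occurrences=occ,
        projected_pattern=pattern,
        per_subject_rates=rates,
        pooled_rate=pooled,
    )


def qpp_regressor(series: ImageSeries, qpp: QPP, stc: np.ndarray | None = None) -> np.ndarray:
    """The QPP's image series: template convolved with the STC, per segment.

    ``r_v(t) = sum_tau stc(tau) * template_v(t - tau)`` with tau running over
    window starts; the linear convolution is truncated to each subject's
    frame range so patterns never bleed across subjects.
    """
    W = qpp.window
    if stc is None:
        stc = qpp.stc
        if stc is None or len(stc) != series.n_frames - W + 1:
            stc = compute_stc(series, qpp.template)
    reg = np.zeros_like(series.data)
    for _, start, n in series.subjects:
        seg_stc = stc[start : start + n - W + 1]
        conv = fftconvolve(qpp.template, seg_stc[np.newaxis, :], axes=1)
        reg[:, start : start + n] = conv[:, :n]
    return reg


def regress_qpp(
    series: ImageSeries, qpp: QPP, return_flags: bool = False
):
    """Residual series after voxel-wise least-squares removal of the QPP.

    Each voxel is fit on [intercept, its own regressor] over the whole
    concatenated series. Voxels whose regressor has zero variance are passed
    through unchanged and flagged.
    """
    if qpp.template.shape[0] != series.n_voxels:
        raise ValueError("voxel count mismatch")
    r = qpp_regressor(series, qpp)
    x = series.data
    rc = r - r.mean(axis=1, keepdims=True)
    var = (rc * rc).sum(axis=1)
    flags = var <= 1e-300
    safe_var = np.where(flags, 1.0, var)
    beta = (x * rc).sum(axis=1) / safe_var
    resid = x - x.mean(axis=1, keepdims=True) - beta[:, np.newaxis] * rc
    resid[flags] = x[flags]
    out = series.with_data(resid)
    if return_flags:
        return out, flags
    return out
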