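"""Temporal preprocessing of masked BOLD series.

Implements the tail of a standard rodent rsfMRI pipeline, applied per
subject segment: temporal band-pass (0.01-0.2 Hz), quadratic detrending
(QDT), voxel-wise global signal regression (GSR) and normalisation to unit
variance. Spatial steps (realignment, normalisation, smoothing) are out of
scope and assumed done upstream.

The band-pass is a zero-phase forward-backward Butterworth (order 4):
only the band is prescribed by convention, and zero-phase filtering is
required because downstream peak-timing analysis cannot tolerate phase
distortion. GSR regresses each voxel on [intercept, mask-mean signal].
Variance normalisation uses the unbiased (n-1) estimator.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .io_types import ImageSeries

__all__ = [
    "quadratic_detrend",
    "bandpass",
    "global_signal_regress",
    "unit_variance",
    "preprocess_chain",
]


def _segments(series: ImageSeries):
    for sid, start, n in series.subjects:
        yield sid, slice(start, start + n)


def quadratic_detrend(series: ImageSeries) -> ImageSeries:
    """Remove the least-squares quadratic trend per voxel, per subject."""
    out = np.empty_like(series.data)
    for sid, seg in _segments(series):
        x = series.data[:, seg]
        n = x.shape[1]
        if n < 4:
            raise ValueError(f"subject {sid}: need >= 4 frames to detrend, got {n}")
        t = np.linspace(-1.0, 1.0, n)
        design = np.vander(t, 3, increasing=True)  # [1, t, t^2]
        q, _ = np.linalg.qr(design)
        out[:, seg] = x - (x @ q) @ q.T
    return series.with_data(out)


def bandpass(
    series: ImageSeries, low_hz: float = 0.01, high_hz: float = 0.2, order: int = 4
) -> ImageSeries:
    """Zero-phase Butterworth band-pass per voxel, per subject segment."""
    nyquist = 1.0 / (2.0 * series.tr_seconds)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyquist}) Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / series.tr_seconds, output="sos")
    out = np.empty_like(series.data)
    for _, seg in _segments(series):
        out[:, seg] = signal.sosfiltfilt(sos, series.data[:, seg], axis=1)
    return series.with_data(out)


def global_signal_regress(series: ImageSeries) -> ImageSeries:
    """Regress the mask-mean time course (plus intercept) out of every voxel."""
    if series.n_voxels < 2:
        raise ValueError("global signal regression needs >= 2 voxels")
    out = np.empty_like(series.data)
    for sid, seg in _segments(series):
        x = series.data[:, seg]
        g = x.mean(axis=0)
        gc = g - g.mean()
        denom = gc @ gc
        if denom <= 1e-300:
            warnings.warn(f"subject {sid}: zero-variance global signal; skipping GSR")
            out[:, seg] = x
            continue
        beta = (x @ gc) / denom
        out[:, seg] = x - x.mean(axis=1, keepdims=True) - np.outer(beta, gc)
    return series.with_data(out)


def unit_variance(series: ImageSeries, return_flags: bool = False):
    """Scale each voxel to unit sample variance per subject segment.

    Zero-variance voxels are set to 0 and flagged rather than erroring.
    """
    out = np.empty_like(series.data)
    flags = np.zeros(series.n_voxels, dtype=bool)
    for _, seg in _segments(series):
        x = series.data[:, seg]
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        degenerate = sd[:, 0] <= 1e-300
        flags |= degenerate
        sd[degenerate] = 1.0
        res = (x - mu) / sd
        res[degenerate] = 0.0
        out[:, seg] = res
    result = series.with_data(out)
    if return_flags:
        return result, flags
    return result


def preprocess_chain(
    series: ImageSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.2,
    steps: tuple[str, ...] = ("filter", "qdt", "gsr", "zvar"),
) -> ImageSeries:
    """Run the preprocessing steps in the given order (default: the full chain)."""
    ops = {
        "filter": lambda s: bandpass(s, low_hz, high_hz),
        "qdt": quadratic_detrend,
        "gsr": global_signal_regress,
        "zvar": unit_variance,
    }
    for step in steps:
        if step not in ops:
            raise ValueError(f"unknown step {step!r}")
        series = ops[step](series)
    return series
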