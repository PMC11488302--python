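"""Synthetic multi-subject BOLD-like data with embedded quasi-periodic motifs.

The generator emulates the temporal structure of a fast rodent rsfMRI
acquisition (TR 0.5 s, 1200 repetitions per subject by default) on a small
phantom grid. Two anticorrelated "networks" of rectangular regions stand in
for the default-mode-like (DMLN) and lateral cortical (LCN) networks; short
(6-frame) and long (20-frame) motifs recur quasi-periodically with
configurable per-region amplitudes and inter-regional peak lags, on top of
i.i.d. Gaussian noise and a per-voxel low-order polynomial drift. Every
occurrence is recorded so downstream stages can be scored against ground
truth.

The occurrence process is jittered-periodic rather than Poisson: onsets are
spaced by the nominal inter-onset interval plus/minus uniform jitter of 25%
of that interval, rejected when closer than one window to the previous onset
or to segment edges. This honours the quasi-periodicity of the patterns and
yields sliding-template-correlation traces with well-separated local maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_types import Atlas, ImageSeries

__all__ = [
    "MotifSpec",
    "GroundTruth",
    "TwoGroupConfig",
    "make_phantom_atlas",
    "simulate_series",
    "two_group_dataset",
    "match_occurrences",
]

JITTER_FRACTION = 0.25  # jitter = +/-25% of the mean inter-onset interval


@dataclass
class MotifSpec:
    """A spatiotemporal motif: who activates, how strongly, and when.

    ``window`` is the motif length in frames (6 for short, 20 for long
    patterns). ``region_amplitudes`` maps region name -> signed amplitude
    (positive = activation, negative = deactivation); at least one of each
    sign is required so the motif encodes two anticorrelated networks.
    ``region_lags`` maps region name -> lag in frames; a region's waveform
    is shifted by its lag and truncated at the window edges.

    Waveform: a half-sine (positive lobe) spanning the window for short
    motifs. Long (even-window) motifs place a half-sine peak in the first
    half of the window and a sign-flipped half-sine in the second half,
    encoding the flux from one network's activation to its deactivation.
    """

    window: int
    region_amplitudes: dict[str, float]
    region_lags: dict[str, float] = field(default_factory=dict)
    two_lobes: bool | None = None  # default: True iff window >= 10 and even

    def __post_init__(self) -> None:
        amps = np.array(list(self.region_amplitudes.values()))
        if not (np.any(amps > 0) and np.any(amps < 0)):
            raise ValueError("motif needs at least one positive and one negative amplitude")
        for name, lag in self.region_lags.items():
            if abs(lag) >= self.window / 2:
                raise ValueError(f"|lag| must be < window/2 (region {name})")
        if self.two_lobes is None:
            self.two_lobes = self.window >= 10 and self.window % 2 == 0

    def waveform(self, region: str) -> np.ndarray:
        """Unit-amplitude lag-shifted waveform of one region, length ``window``."""
        W = self.window
        lag = self.region_lags.get(region, 0.0)
        t = np.arange(W, dtype=np.float64) - lag
        if self.two_lobes:
            half = W / 2.0
            w = np.where(
                (t >= 0) & (t < half),
                np.sin(np.pi * (t + 0.5) / half),
                0.0,
            )
            w = w + np.where(
                (t >= half) & (t < W),
                -np.sin(np.pi * (t - half + 0.5) / half),
                0.0,
            )
        else:
            w = np.where((t >= 0) & (t < W), np.sin(np.pi * (t + 0.5) / W), 0.0)
        return w

    def template(self, atlas: Atlas, series_coords: np.ndarray) -> np.ndarray:
        """Noiseless voxel x window template on the series' voxel grid."""
        labels = atlas.labels[tuple(series_coords.T)]
        V = len(labels)
        tpl = np.zeros((V, self.window))
        for name, amp in self.region_amplitudes.items():
            lab = atlas.label_of(name)
            tpl[labels == lab] = amp * self.waveform(name)
        return tpl


@dataclass
class GroundTruth:
    """What the generator actually embedded, for parameter-recovery scoring."""

    occurrences: dict[str, dict[int, list[int]]]  # subject -> motif idx -> starts
    templates: list[np.ndarray]  # motif idx -> (V, W) noiseless template
    params: dict

    def all_occurrences(self, motif: int) -> np.ndarray:
        out = []
        for sub in self.occurrences.values():
            out.extend(sub.get(motif, []))
        return np.array(sorted(out), dtype=int)


def make_phantom_atlas(
    shape: tuple[int, int, int] = (20, 20, 4),
    n_regions_per_network: int = 3,
    region_size: tuple[int, int, int] | None = None,
) -> tuple[Atlas, np.ndarray]:
    """Rectangular phantom atlas with two networks of disjoint block regions.

    Regions are laid out on a grid in the first two axes, half assigned to a
    default-mode-like network ("DMLN-like"), half to a lateral-cortical-like
    network ("LCN-like"). The mask is the union of the regions plus the
    unlabeled background voxels of the bounding grid.
    """
    shape = tuple(int(s) for s in shape)
    n_total = 2 * n_regions_per_network
    # place blocks on an nx x ny grid of cells
    nx = int(np.ceil(np.sqrt(n_total)))
    ny = int(np.ceil(n_total / nx))
    cell = (shape[0] // nx, shape[1] // ny)
    if cell[0] < 3 or cell[1] < 3 or shape[2] < 1:
        raise ValueError(f"shape {shape} too small for {n_total} block regions")
    if region_size is None:
        region_size = (max(2, cell[0] - 1), max(2, cell[1] - 1), max(1, shape[2] // 2))
    labels = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    network_of: dict[str, str] = {}
    lab = 0
    for i in range(n_total):
        cx, cy = i % nx, i // nx
        x0, y0 = cx * cell[0], cy * cell[1]
        lab += 1
        sx = slice(x0, min(x0 + region_size[0], shape[0]))
        sy = slice(y0, min(y0 + region_size[1], shape[1]))
        sz = slice(0, region_size[2])
        labels[sx, sy, sz] = lab
        net = "DMLN-like" if i < n_regions_per_network else "LCN-like"
        name = f"{'D' if net.startswith('D') else 'L'}{(i % n_regions_per_network) + 1}"
        names[lab] = name
        network_of[name] = net
    mask = np.ones(shape, dtype=bool)
    return Atlas(labels=labels, names=names, network_of=network_of), mask


def _draw_onsets(
    rng: np.random.Generator, n_frames: int, window: int, interval: float
) -> list[int]:
    """Jittered-periodic onsets inside one subject segment (segment-local)."""
    onsets: list[int] = []
    t = rng.uniform(0, interval)
    while True:
        onset = int(round(t))
        if onset + window > n_frames:
            break
        if not onsets or onset - onsets[-1] >= window:
            if onset >= 0:
                onsets.append(onset)
        t += interval + rng.uniform(-JITTER_FRACTION, JITTER_FRACTION) * interval
    return onsets


def simulate_series(
    atlas: Atlas,
    mask: np.ndarray,
    motifs: Sequence[MotifSpec],
    rate_per_min: Sequence[float] | float,
    n_subjects: int = 10,
    n_frames: int = 1200,
    tr_seconds: float = 0.5,
    noise_sd: float = 1.0,
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    subject_prefix: str = "sub",
) -> tuple[ImageSeries, GroundTruth]:
    """Simulate a multi-subject series with embedded quasi-periodic motifs.

    Each occurrence adds a motif's lag-shifted, amplitude-scaled waveform to
    its regions' voxels; i.i.d. Gaussian noise (sd ``noise_sd``) and a
    per-voxel quadratic drift are superimposed. The drift triple gives the
    standard deviations of per-voxel random constant / linear / quadratic
    coefficients on a time axis normalised to [-1, 1].

    Subject-level random streams are spawned deterministically from the
    master seed, so adding a subject never perturbs earlier subjects.
    """
    mask = np.asarray(mask).astype(bool)
    coords = np.argwhere(mask)
    V = len(coords)
    motifs = list(motifs)
    if np.isscalar(rate_per_min):
        rate_per_min = [float(rate_per_min)] * len(motifs)
    if len(rate_per_min) != len(motifs):
        raise ValueError("need one rate per motif")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    minutes = n_frames * tr_seconds / 60.0
    for m, rate in zip(motifs, rate_per_min):
        if rate * minutes * m.window >= 0.8 * n_frames:
            raise ValueError(
                f"rate {rate}/min with window {m.window} would fill >80% of frames"
            )

    templates = [m.template(atlas, coords) for m in motifs]
    master = np.random.SeedSequence(seed)
    streams = [np.random.Generator(np.random.PCG64(s)) for s in master.spawn(n_subjects)]

    data = np.empty((V, n_subjects * n_frames))
    occurrences: dict[str, dict[int, list[int]]] = {}
    subjects = []
    u = np.linspace(-1.0, 1.0, n_frames)
    for j in range(n_subjects):
        rng = streams[j]
        sid = f"{subject_prefix}{j + 1:02d}"
        block = rng.normal(0.0, noise_sd, size=(V, n_frames))
        if any(d != 0 for d in drift):
            coeffs = rng.normal(0.0, 1.0, size=(V, 3)) * np.asarray(drift)
            block += coeffs @ np.vstack([np.ones_like(u), u, u * u])
        sub_occ: dict[int, list[int]] = {}
        for mi, (m, rate) in enumerate(zip(motifs, rate_per_min)):
            if rate <= 0:
                sub_occ[mi] = []
                continue
            interval = 60.0 / (rate * tr_seconds)  # frames between onsets
            onsets = _draw_onsets(rng, n_frames, m.window, interval)
            for o in onsets:
                block[:, o : o + m.window] += templates[mi]
            sub_occ[mi] = [o + j * n_frames for o in onsets]  # global frames
        occurrences[sid] = sub_occ
        data[:, j * n_frames : (j + 1) * n_frames] = block
        subjects.append((sid, j * n_frames, n_frames))

    series = ImageSeries(
        data=data,
        tr_seconds=tr_seconds,
        subjects=subjects,
        voxel_coords=coords,
        mask_shape=mask.shape,
    )
    gt = GroundTruth(
        occurrences=occurrences,
        templates=templates,
        params={
            "rate_per_min": list(map(float, rate_per_min)),
            "noise_sd": noise_sd,
            "drift": list(drift),
            "seed": seed,
            "n_subjects": n_subjects,
            "n_frames": n_frames,
            "tr_seconds": tr_seconds,
        },
    )
    return series, gt


def match_occurrences(
    found: np.ndarray, truth: np.ndarray, tol: int = 2
) -> tuple[float, float]:
    """Score detected occurrence frames against ground truth.

    Returns ``(recall, false_rate)``: the fraction of true occurrences with a
    detection within ``tol`` frames, and the fraction of detections further
    than ``tol`` frames from any true occurrence.
    """
    found = np.asarray(found, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if len(truth) == 0:
        return float("nan"), 0.0 if len(found) == 0 else 1.0
    if len(found) == 0:
        return 0.0, 0.0
    recall = float(np.mean([np.min(np.abs(found - t)) <= tol for t in truth]))
    false_rate = float(np.mean([np.min(np.abs(truth - f)) > tol for f in found]))
    return recall, false_rate


@dataclass
class TwoGroupConfig:
    """Group-level differences for a two-group synthetic experiment.

    Group B's occurrence rates are scaled by ``rate_multiplier_B`` and its
    motif amplitudes region-wise by ``amplitude_multipliers_B`` (default 1.0
    everywhere), emulating a reduced-occurrence / altered-activation disease
    group against a wild-type-like group A.
    """

    motifs: Sequence[MotifSpec]
    rate_per_min: Sequence[float] | float = 1.0
    rate_multiplier_B: float | Sequence[float] = 1.0
    amplitude_multipliers_B: Mapping[str, float] | None = None
    lag_shifts_B: Mapping[str, float] | None = None
    n_subjects: int = 10
    n_frames: int = 1200
    tr_seconds: float = 0.5
    noise_sd: float = 1.0
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0


def two_group_dataset(
    atlas: Atlas, mask: np.ndarray, config: TwoGroupConfig
) -> tuple[ImageSeries, ImageSeries, GroundTruth, GroundTruth]:
    """Two independent datasets sharing the atlas, differing by group effects."""
    motifs = list(config.motifs)
    rates = config.rate_per_min
    if np.isscalar(rates):
        rates = [float(rates)] * len(motifs)
    mult = config.rate_multiplier_B
    if np.isscalar(mult):
        mult = [float(mult)] * len(motifs)
    rates_b = [r * m for r, m in zip(rates, mult)]

    motifs_b = []
    for m in motifs:
        amps = dict(m.region_amplitudes)
        if config.amplitude_multipliers_B:
            for name, f in config.amplitude_multipliers_B.items():
                if name in amps:
                    amps[name] = amps[name] * f
        lags = dict(m.region_lags)
        if config.lag_shifts_B:
            for name, d in config.lag_shifts_B.items():
                lags[name] = lags.get(name, 0.0) + d
        motifs_b.append(
            MotifSpec(
                window=m.window,
                region_amplitudes=amps,
                region_lags=lags,
                two_lobes=m.two_lobes,
            )
        )

    series_a, gt_a = simulate_series(
        atlas, mask, motifs, rates,
        n_subjects=config.n_subjects, n_frames=config.n_frames,
        tr_seconds=config.tr_seconds, noise_sd=config.noise_sd,
        drift=config.drift, seed=config.seed, subject_prefix="A",
    )
    series_b, gt_b = simulate_series(
        atlas, mask, motifs_b, rates_b,
        n_subjects=config.n_subjects, n_frames=config.n_frames,
        tr_seconds=config.tr_seconds, noise_sd=config.noise_sd,
        drift=config.drift, seed=config.seed + 1_000_003, subject_prefix="B",
    )
    return series_a, series_b, gt_a, gt_b
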