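"""Shared domain types and I/O for masked BOLD image series.

The central carrier is :class:`ImageSeries`: a voxel x time matrix holding
the brain-masked BOLD values of one or more subjects concatenated along
time, together with the subject partition, the repetition time (TR) and the
voxel -> 3D-grid coordinate map needed to go back to volume space.

Voxels are flattened in C-order over the 3D grid restricted to mask-true
voxels; this order is fixed and stable across runs so voxel indices are
reproducible. Frames are 0-based; subject segments are half-open
``[start, start + n_frames)``; all occurrence frames elsewhere in the
package refer to window START frames.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageSeries",
    "Atlas",
    "load_subject_series",
    "frame_to_subject",
    "write_results",
    "read_series",
    "write_series",
    "read_qpp",
]


@dataclass
class ImageSeries:
    """Masked multi-subject BOLD series.

    Parameters
    ----------
    data:
        ``(V, T)`` float array, V mask voxels by T concatenated frames.
    tr_seconds:
        Repetition time in seconds (0.5 for the emulated acquisition).
    subjects:
        Ordered ``(subject_id, start_frame, n_frames)`` triples partitioning
        ``[0, T)`` contiguously and without overlap.
    voxel_coords:
        ``(V, 3)`` integer indices into the source volume grid.
    mask_shape:
        3D extents of the source grid.
    """

    data: np.ndarray
    tr_seconds: float
    subjects: list[tuple[str, int, int]]
    voxel_coords: np.ndarray
    mask_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=np.int64)
        self.mask_shape = tuple(int(s) for s in self.mask_shape)
        if self.data.ndim != 2:
            raise ValueError("data must be a (V, T) matrix")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.voxel_coords.shape != (self.n_voxels, 3):
            raise ValueError("voxel_coords must be (V, 3)")
        # subject segments: contiguous, non-overlapping, covering [0, T)
        cursor = 0
        for sid, start, n in self.subjects:
            if start != cursor or n <= 0:
                raise ValueError("subject segments must tile [0, T) contiguously")
            cursor += n
        if cursor != self.n_frames:
            raise ValueError("subject segments must cover exactly [0, T)")
        if np.any(self.voxel_coords < 0) or np.any(
            self.voxel_coords >= np.asarray(self.mask_shape)
        ):
            raise ValueError("voxel coordinate outside mask grid")
        flat = np.ravel_multi_index(self.voxel_coords.T, self.mask_shape)
        if len(np.unique(flat)) != self.n_voxels:
            raise ValueError("voxel_coords entries must be unique")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.subjects]

    def subject_slice(self, subject_id: str) -> slice:
        for sid, start, n in self.subjects:
            if sid == subject_id:
                return slice(start, start + n)
        raise KeyError(subject_id)

    def with_data(self, data: np.ndarray) -> "ImageSeries":
        """Copy of this series carrying new values on the same grid/partition."""
        return ImageSeries(
            data=data,
            tr_seconds=self.tr_seconds,
            subjects=list(self.subjects),
            voxel_coords=self.voxel_coords,
            mask_shape=self.mask_shape,
        )

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values back onto the 3D grid."""
        values = np.asarray(values)
        vol = np.full(self.mask_shape, fill, dtype=values.dtype)
        vol[tuple(self.voxel_coords.T)] = values
        return vol


@dataclass
class Atlas:
    """Integer region-label volume with a name lookup and optional networks."""

    labels: np.ndarray
    names: dict[int, str]
    network_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def region_names(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]

    def label_of(self, name: str) -> int:
        for k, v in self.names.items():
            if v == name:
                return k
        raise KeyError(name)

    def region_voxel_indices(self, series: ImageSeries, name: str) -> np.ndarray:
        """Indices (into the series voxel axis) of a region's voxels."""
        lab = self.labels[tuple(series.voxel_coords.T)]
        return np.flatnonzero(lab == self.label_of(name))


def load_subject_series(
    paths: Sequence[str | os.PathLike],
    mask: np.ndarray,
    tr_seconds: float,
    subject_ids: Sequence[str] | None = None,
) -> ImageSeries:
    """Load per-subject 4D NIfTI volumes, mask them and concatenate along time.

    Voxels inside the mask are flattened in C-order over the 3D grid;
    subjects are concatenated in input order and the partition is recorded.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no voxels")
    coords = np.argwhere(mask)  # C-order scan of the grid
    if subject_ids is None:
        subject_ids = [
            os.path.basename(str(p)).split(".nii")[0] for p in paths
        ]
    blocks: list[np.ndarray] = []
    subjects: list[tuple[str, int, int]] = []
    cursor = 0
    for sid, p in zip(subject_ids, paths):
        img = nib.load(str(p))
        vol = np.asarray(img.dataobj, dtype=np.float64)
        if vol.ndim != 4:
            raise ValueError(f"{p}: expected a 4D volume")
        if vol.shape[:3] != mask.shape:
            raise ValueError(
                f"{p}: grid {vol.shape[:3]} does not match mask {mask.shape}"
            )
        if vol.shape[3] < 2:
            raise ValueError(f"{p}: needs at least 2 frames")
        blocks.append(vol[mask, :])
        subjects.append((sid, cursor, vol.shape[3]))
        cursor += vol.shape[3]
    return ImageSeries(
        data=np.concatenate(blocks, axis=1),
        tr_seconds=tr_seconds,
        subjects=subjects,
        voxel_coords=coords,
        mask_shape=mask.shape,
    )


def frame_to_subject(series: ImageSeries, frame: int) -> str:
    """Subject whose half-open segment contains ``frame``."""
    frame = int(frame)
    if frame < 0 or frame >= series.n_frames:
        raise IndexError(f"frame {frame} outside [0, {series.n_frames})")
    starts = np.array([s for _, s, _ in series.subjects])
    k = int(np.searchsorted(starts, frame, side="right")) - 1
    return series.subjects[k][0]


def frames_to_subjects(series: ImageSeries, frames: np.ndarray) -> np.ndarray:
    """Vectorised :func:`frame_to_subject`; returns an array of subject ids."""
    frames = np.asarray(frames, dtype=np.int64)
    if frames.size and (frames.min() < 0 or frames.max() >= series.n_frames):
        raise IndexError("frame outside series")
    starts = np.array([s for _, s, _ in series.subjects])
    idx = np.searchsorted(starts, frames, side="right") - 1
    ids = np.array(series.subject_ids, dtype=object)
    return ids[idx]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_series(series: ImageSeries, path: str | os.PathLike) -> None:
    """Round-trippable container for an ImageSeries (HDF5)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=series.data)
        f.create_dataset("voxel_coords", data=series.voxel_coords)
        f.attrs["tr_seconds"] = series.tr_seconds
        f.attrs["mask_shape"] = series.mask_shape
        sub = np.array(
            [(sid, start, n) for sid, start, n in series.subjects],
            dtype=[("id", "S64"), ("start", "i8"), ("n", "i8")],
        )
        f.create_dataset("subjects", data=sub)


def read_series(path: str | os.PathLike) -> ImageSeries:
    with h5py.File(path, "r") as f:
        subjects = [
            (row["id"].decode(), int(row["start"]), int(row["n"]))
            for row in f["subjects"][()]
        ]
        return ImageSeries(
            data=f["data"][()],
            tr_seconds=float(f.attrs["tr_seconds"]),
            subjects=subjects,
            voxel_coords=f["voxel_coords"][()],
            mask_shape=tuple(int(s) for s in f.attrs["mask_shape"]),
        )


def _template_to_nifti(template: np.ndarray, series: ImageSeries) -> nib.Nifti1Image:
    """Voxel x window template -> 4D NIfTI (window on the 4th axis), float32."""
    V, W = template.shape
    vol = np.zeros(series.mask_shape + (W,), dtype=np.float32)
    vol[tuple(series.voxel_coords.T)] = template.astype(np.float32)
    return nib.Nifti1Image(vol, affine=np.eye(4))


def write_results(bundle, path: str | os.PathLike, series: ImageSeries | None = None,
                  meta: Mapping | None = None) -> dict:
    """Serialize a result object to a directory; returns a manifest.

    QPP templates go out as 4D NIfTI (window as the 4th axis, float32 per the
    storage convention); occurrence tables and matrices as CSV (float64);
    run metadata as JSON. The manifest lists every file written.
    """
    from .qpp_extract import QPP  # local import to avoid a cycle
    from .qpp_apply import Projection

    path = str(path)
    os.makedirs(path, exist_ok=True)
    manifest: dict = {"files": [], "kind": type(bundle).__name__}

    def _add(name: str) -> str:
        manifest["files"].append(name)
        return os.path.join(path, name)

    if isinstance(bundle, QPP):
        if series is None:
            raise ValueError("writing a QPP requires the source ImageSeries")
        nib.save(_template_to_nifti(bundle.template, series), _add("template.nii.gz"))
        pd.DataFrame({"stc": bundle.stc}).to_csv(_add("stc.csv"), index=False)
        pd.DataFrame({"start_frame": np.asarray(bundle.occurrences, dtype=int)}).to_csv(
            _add("occurrences.csv"), index=False
        )
        info = {
            "window": int(bundle.window),
            "threshold": float(bundle.threshold),
            "n_iterations": int(bundle.n_iterations),
            "seed_frame": int(bundle.seed_frame),
            "converged": bool(bundle.converged),
        }
        if meta:
            info.update(meta)
        with open(_add("qpp.json"), "w") as f:
            json.dump(info, f, indent=2, sort_keys=True)
    elif isinstance(bundle, Projection):
        pd.DataFrame({"stc": bundle.target_stc}).to_csv(_add("stc.csv"), index=False)
        pd.DataFrame(
            {"start_frame": np.asarray(bundle.target_occurrences, dtype=int)}
        ).to_csv(_add("occurrences.csv"), index=False)
        pd.DataFrame(
            sorted(bundle.per_subject_rates.items()),
            columns=["subject", "rate_per_min"],
        ).to_csv(_add("rates.csv"), index=False)
        if meta:
            with open(_add("meta.json"), "w") as f:
                json.dump(dict(meta), f, indent=2, sort_keys=True)
    elif isinstance(bundle, pd.DataFrame):
        bundle.to_csv(_add("table.csv"), index=False)
        if meta:
            with open(_add("meta.json"), "w") as f:
                json.dump(dict(meta), f, indent=2, sort_keys=True)
    else:
        raise TypeError(f"cannot serialize {type(bundle).__name__}")

    with open(os.path.join(path, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def read_qpp(path: str | os.PathLike, series: ImageSeries):
    """Inverse of :func:`write_results` for a QPP directory."""
    from .qpp_extract import QPP

    path = str(path)
    img = nib.load(os.path.join(path, "template.nii.gz"))
    vol = np.asarray(img.dataobj, dtype=np.float64)
    template = vol[tuple(series.voxel_coords.T)]
    stc = pd.read_csv(os.path.join(path, "stc.csv"))["stc"].to_numpy()
    occ = pd.read_csv(os.path.join(path, "occurrences.csv"))
    occurrences = occ["start_frame"].to_numpy(dtype=int) if len(occ) else np.array([], dtype=int)
    with open(os.path.join(path, "qpp.json")) as f:
        info = json.load(f)
    return QPP(
        template=template,
        window=info["window"],
        stc=stc,
        occurrences=occurrences,
        threshold=info["threshold"],
        n_iterations=info["n_iterations"],
        seed_frame=info["seed_frame"],
        converged=info["converged"],
    )
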