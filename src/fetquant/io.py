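"""Volumetric containers and NIfTI-1 input/output.

The package operates on three kinds of grid-bearing objects: a static 3D
uptake volume (:class:`ImageVolume`), a binary mask on the same kind of grid
(:class:`BinaryMask`), and a dynamic acquisition (:class:`DynamicSeries`, an
ordered stack of frames with a :class:`FrameTiming` schedule).  All world
coordinates are millimetres, obtained from the voxel-index-to-world affine;
voxel indices are 0-based.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "FrameTiming",
    "DynamicSeries",
    "read_volume",
    "read_mask",
    "read_series",
    "read_frame_timing",
    "write_volume",
    "write_mask",
    "write_series",
    "write_frame_timing",
    "check_grid_compatible",
    "require_grid_compatible",
    "summed_image",
]

#: Default tolerance (mm) for element-wise affine agreement.
DEFAULT_GRID_TOL = 1e-3


def _validate_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("degenerate affine: spatial 3x3 block is singular")
    return affine


class _GridMixin:
    """Shared geometry helpers for grid-bearing objects."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (voxel centres)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        out = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if np.asarray(indices).ndim == 1 else out

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        out = pts @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if np.asarray(points_mm).ndim == 1 else out


@dataclass
class ImageVolume(_GridMixin):
    """A 3D scalar uptake grid with voxel spacing and voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"ImageVolume requires 3D data, got {self.data.ndim}D; "
                "use read_series for 4D dynamic images"
            )
        self.affine = _validate_affine(self.affine)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")


@dataclass
class BinaryMask(_GridMixin):
    """A boolean 3D grid sharing the geometry conventions of ImageVolume."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"BinaryMask requires 3D data, got {self.data.ndim}D")
        self.affine = _validate_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass
class FrameTiming:
    """Per-frame acquisition schedule, seconds post-injection.

    ``start_s[i]`` is the start of frame *i* and ``duration_s[i]`` its length.
    Frames must be ordered, non-overlapping, and fit within the configured
    acquisition span (40 min by default for a standard dynamic FET protocol).
    """

    start_s: np.ndarray
    duration_s: np.ndarray
    acquisition_min: float = 40.0

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        if self.start_s.ndim != 1 or self.start_s.shape != self.duration_s.shape:
            raise ValueError("start_s and duration_s must be 1D arrays of equal length")
        if len(self.start_s) == 0:
            raise ValueError("timing requires at least one frame")
        if np.any(self.duration_s <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(self.start_s) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = self.start_s + self.duration_s
        if np.any(self.start_s[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames overlap")
        if ends[-1] > self.acquisition_min * 60.0 + 1e-6:
            raise ValueError(
                f"schedule extends to {ends[-1]:.0f} s, beyond the "
                f"{self.acquisition_min:.0f}-min acquisition"
            )

    def __len__(self) -> int:
        return len(self.start_s)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times in minutes post-injection."""
        return (self.start_s + self.duration_s / 2.0) / 60.0

    @classmethod
    def uniform(cls, n_frames: int = 8, frame_s: float = 300.0,
                acquisition_min: float = 40.0) -> "FrameTiming":
        """Uniform schedule; the default 8 x 300 s covers 0-40 min."""
        starts = np.arange(n_frames) * frame_s
        return cls(starts, np.full(n_frames, frame_s), acquisition_min)


@dataclass
class DynamicSeries:
    """An ordered stack of frames on one shared grid plus frame timing."""

    frames: list[ImageVolume]
    timing: FrameTiming

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("series requires at least one frame")
        if len(self.frames) != len(self.timing):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.timing)} timing entries"
            )
        first = self.frames[0]
        for f in self.frames[1:]:
            if not check_grid_compatible(first, f):
                raise ValueError("all frames must share one grid")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def affine(self) -> np.ndarray:
        return self.frames[0].affine

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames[0].grid_shape

    def as_array(self) -> np.ndarray:
        """Stack frame data into a 4D array (x, y, z, t)."""
        return np.stack([f.data for f in self.frames], axis=-1)


# ---------------------------------------------------------------------------
# NIfTI-1 reading / writing


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI-1 file as an :class:`ImageVolume`.

    Trailing singleton dimensions are squeezed; a true 4D file is rejected
    with a pointer to :func:`read_series`.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    data = _squeeze_trailing(data)
    if data.ndim == 4:
        raise ValueError(
            f"{path} is a 4D image; use read_series for dynamic acquisitions"
        )
    if data.ndim != 3:
        raise ValueError(f"{path} has {data.ndim} spatial dimensions, expected 3")
    return ImageVolume(data, img.affine)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI-1 label image as a binary mask (voxels > 0.5 are true)."""
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.affine)


def _squeeze_trailing(data: np.ndarray) -> np.ndarray:
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    return data


def read_frame_timing(path: str | Path, acquisition_min: float = 40.0) -> FrameTiming:
    """Read a frame-timing sidecar.

    JSON files use the BIDS-PET dialect with arrays ``FrameTimesStart`` and
    ``FrameDuration`` (seconds); CSV files need columns ``start_s,duration_s``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        sidecar = json.loads(path.read_text())
        try:
            start = sidecar["FrameTimesStart"]
            dur = sidecar["FrameDuration"]
        except KeyError as exc:
            raise ValueError(
                f"{path}: JSON sidecar must contain FrameTimesStart and FrameDuration"
            ) from exc
        return FrameTiming(start, dur, acquisition_min)
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows or "start_s" not in rows[0] or "duration_s" not in rows[0]:
        raise ValueError(f"{path}: CSV sidecar needs columns start_s,duration_s")
    start = [float(r["start_s"]) for r in rows]
    dur = [float(r["duration_s"]) for r in rows]
    return FrameTiming(start, dur, acquisition_min)


def read_series(path: str | Path, timing_path: str | Path,
                acquisition_min: float = 40.0) -> DynamicSeries:
    """Read a 4D NIfTI-1 dynamic acquisition with its timing sidecar."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"{path} has {data.ndim} dimensions, expected 4D dynamic")
    timing = read_frame_timing(timing_path, acquisition_min)
    if data.shape[3] != len(timing):
        raise ValueError(
            f"{path} has {data.shape[3]} frames but the sidecar lists {len(timing)}"
        )
    frames = [ImageVolume(data[..., t], img.affine) for t in range(data.shape[3])]
    return DynamicSeries(frames, timing)


def write_volume(vol: ImageVolume | BinaryMask, path: str | Path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    write_volume(mask, path)


def write_series(series: DynamicSeries, path: str | Path,
                 timing_path: str | Path | None = None) -> None:
    nib.save(nib.Nifti1Image(series.as_array(), series.affine), str(path))
    if timing_path is not None:
        write_frame_timing(series.timing, timing_path)


def write_frame_timing(timing: FrameTiming, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({
            "FrameTimesStart": timing.start_s.tolist(),
            "FrameDuration": timing.duration_s.tolist(),
        }, indent=1))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["start_s", "duration_s"])
            for s, d in zip(timing.start_s, timing.duration_s):
                writer.writerow([s, d])


# ---------------------------------------------------------------------------
# Grid compatibility and summed images


def check_grid_compatible(a, b, tol: float = DEFAULT_GRID_TOL) -> bool:
    """True iff two grid-bearing objects share shape and affine within tol (mm)."""
    if tuple(a.grid_shape) != tuple(b.grid_shape):
        return False
    return bool(np.all(np.abs(np.asarray(a.affine) - np.asarray(b.affine)) <= tol))


def require_grid_compatible(a, b, tol: float = DEFAULT_GRID_TOL,
                            what: str = "inputs") -> None:
    if not check_grid_compatible(a, b, tol):
        raise ValueError(
            f"{what} are not grid-compatible: shapes {a.grid_shape} vs "
            f"{b.grid_shape}, or affines differ by more than {tol} mm"
        )


def summed_image(series: DynamicSeries, window_start_min: float = 20.0,
                 window_end_min: float = 40.0) -> ImageVolume:
    """Collapse the frames of a late time window into one static image.

    Frames are selected by mid-time within the closed window and combined as
    a duration-weighted mean.  The defaults reproduce the standard late
    (20-40 min) summed FET image of a 40-min dynamic acquisition.
    """
    if window_end_min <= window_start_min:
        raise ValueError("window_end_min must exceed window_start_min")
    mids = series.timing.mid_times_min
    sel = (mids >= window_start_min) & (mids <= window_end_min)
    if not sel.any():
        raise ValueError(
            f"no frame mid-time falls in [{window_start_min}, {window_end_min}] min"
        )
    weights = series.timing.duration_s[sel]
    stack = np.stack([series.frames[i].data for i in np.flatnonzero(sel)], axis=-1)
    data = (stack * weights).sum(axis=-1) / weights.sum()
    return ImageVolume(data, series.affine)
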