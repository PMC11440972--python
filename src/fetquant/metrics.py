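"""Semi-quantitative clinical PET metrics over a delineated tumor volume.

TBR_mean and TBR_max are the mean and maximum uptake inside the BTV divided
by the background-ROI mean; BTV is the delineated volume in ml; the peak
location is the world-mm position of the hottest BTV voxel, the usual biopsy
planning target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .delineation import label_components
from .io import BinaryMask, ImageVolume, require_grid_compatible

__all__ = ["LesionMetrics", "btv_ml", "tbr_metrics", "peak_location",
           "peak_distance_mm", "lesion_metrics"]


@dataclass
class LesionMetrics:
    """Scan- or component-level metric bundle.

    For an empty mask the TBR values and peak location are NaN ("no
    FET-positive lesion"), never zero, so concordance analyses can drop
    non-detections instead of biasing fits.
    """

    btv_ml: float
    tbr_mean: float
    tbr_max: float
    peak_location_mm: tuple[float, float, float]
    peak_ties: int
    n_components: int = 1

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.tbr_mean)

    @classmethod
    def missing(cls) -> "LesionMetrics":
        nan = float("nan")
        return cls(0.0, nan, nan, (nan, nan, nan), 0, 0)


def btv_ml(mask: BinaryMask) -> float:
    """Delineated volume in ml (voxel count x voxel volume / 1000)."""
    return mask.volume_ml


def tbr_metrics(image: ImageVolume, mask: BinaryMask,
                bg_mean: float) -> tuple[float, float]:
    """(TBR_mean, TBR_max) over the mask; (nan, nan) for an empty mask."""
    if bg_mean <= 0:
        raise ValueError("background mean must be positive")
    require_grid_compatible(image, mask, what="image and mask")
    if mask.is_empty():
        return float("nan"), float("nan")
    vals = image.data[mask.data]
    return float(vals.mean() / bg_mean), float(vals.max() / bg_mean)


def peak_location(image: ImageVolume,
                  mask: BinaryMask) -> tuple[tuple[float, float, float], int]:
    """World-mm centre of the hottest voxel inside the mask.

    Ties are broken deterministically by the lowest linear index in scan
    order; the number of tied voxels is returned alongside.
    """
    require_grid_compatible(image, mask, what="image and mask")
    if mask.is_empty():
        raise ValueError("peak location of an empty mask is undefined")
    flat_idx = np.flatnonzero(mask.data.ravel())
    vals = image.data.ravel()[flat_idx]
    vmax = vals.max()
    tied = flat_idx[vals == vmax]
    winner = int(tied.min())
    ijk = np.unravel_index(winner, image.grid_shape)
    world = image.voxel_to_world(np.asarray(ijk, dtype=float))
    return tuple(float(c) for c in world), int(len(tied))


def peak_distance_mm(a, b) -> float:
    """Euclidean world-space distance between two peak locations (mm)."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def lesion_metrics(image: ImageVolume, mask: BinaryMask, bg_mean: float,
                   per_component: bool = False):
    """Metrics for the BTV union and optionally per connected component.

    The union values are the scan-level values; multi-lesion scans get one
    scan-level row plus one row per 26-connected component when
    ``per_component`` is set.
    """
    if mask.is_empty():
        scan = LesionMetrics.missing()
        return (scan, []) if per_component else scan
    comps = label_components(mask)
    mean, mx = tbr_metrics(image, mask, bg_mean)
    loc, ties = peak_location(image, mask)
    scan = LesionMetrics(btv_ml(mask), mean, mx, loc, ties,
                         n_components=len(comps))
    if not per_component:
        return scan
    rows = []
    for c in comps:
        cmean, cmax = tbr_metrics(image, c, bg_mean)
        cloc, cties = peak_location(image, c)
        rows.append(LesionMetrics(btv_ml(c), cmean, cmax, cloc, cties))
    return scan, rows
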