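"""Shared fixtures: small grids, compact phantoms, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from fetquant import BinaryMask, ImageVolume, LesionSpec, PhantomSpec

AFF2 = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic, origin at voxel 0


def make_volume(data, affine=None) -> ImageVolume:
    return ImageVolume(np.asarray(data, float), AFF2 if affine is None else affine)


def make_mask(data, affine=None) -> BinaryMask:
    return BinaryMask(np.asarray(data, bool), AFF2 if affine is None else affine)


def small_spec(**overrides) -> PhantomSpec:
    """A 64^3 phantom that keeps unit tests fast; geometry scaled to fit."""
    kw = dict(
        grid_shape=(64, 64, 64),
        spacing_mm=(2.0, 2.0, 2.0),
        brain_semi_axes_mm=(45.0, 55.0, 40.0),
        lesions=(LesionSpec(center_mm=(20.0, 10.0, 5.0),
                            semi_axes_mm=(8.0, 8.0, 8.0)),),
        noise_sigma=0.0,
        psf_fwhm_mm=0.0,
        seed=0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture
def clean_spec() -> PhantomSpec:
    return small_spec()


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and independent)


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """26-connected components by explicit breadth-first flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp, queue = set(), [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.add(v)
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(comp)
    return comps


def loop_confusion(pred: np.ndarray, ref: np.ndarray,
                   domain: np.ndarray) -> tuple[int, int, int, int]:
    """Triple-loop TP/FP/FN/TN counts restricted to the domain."""
    tp = fp = fn = tn = 0
    nx, ny, nz = pred.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not domain[i, j, k]:
                    continue
                p, r = pred[i, j, k], ref[i, j, k]
                if p and r:
                    tp += 1
                elif p:
                    fp += 1
                elif r:
                    fn += 1
                else:
                    tn += 1
    return tp, fp, fn, tn


def loop_threshold(data: np.ndarray, cut: float,
                   domain: np.ndarray) -> np.ndarray:
    """Triple-loop at-or-above thresholding within a domain."""
    out = np.zeros(data.shape, bool)
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if domain[i, j, k] and data[i, j, k] >= cut:
                    out[i, j, k] = True
    return out
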