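"""Synthetic brain-PET phantoms with ground truth.

Patient FET data is not publicly shareable, so every pipeline stage is
exercised against simulated phantoms: an ellipsoidal brain support with
homogeneous background uptake, one or more ellipsoidal lesions at a
controlled true tumor-to-background ratio, optional extratumoral
confounding hotspots (superior vascular rim, pituitary region, scalp
shell), Gaussian point-spread blurring emulating scanner resolution, and
additive Gaussian voxel noise (a deliberate simplification of PET Poisson
counting statistics).

Ground-truth lesion masks are defined on the ideal, pre-blur, pre-noise
image: recovery tests therefore quantify partial-volume and noise effects
honestly instead of comparing against an already-degraded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .delineation import BackgroundROI
from .dynamics import TimeActivityCurve
from .io import BinaryMask, DynamicSeries, FrameTiming, ImageVolume
from .kinetics import DEFAULT_PATTERN_PARAMS, RiseFall, SaturatingUptake, \
    shape_for_pattern

__all__ = ["LesionSpec", "ConfounderSpec", "PhantomSpec", "StaticPhantom",
           "DynamicPhantom", "generate_static", "generate_dynamic",
           "generate_longitudinal_cohort", "default_background_roi",
           "sample_tac"]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.355


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal lesion with a plateau at ``tbr_true`` x background."""

    center_mm: tuple[float, float, float] = (35.0, 20.0, 10.0)
    semi_axes_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    tbr_true: float = 2.0
    pattern: str = "II"
    kinetic_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tbr_true <= 0:
            raise ValueError("tbr_true must be positive")
        if self.pattern not in ("I", "II", "III"):
            raise ValueError(f"unknown kinetic pattern {self.pattern!r}")
        if min(self.semi_axes_mm) <= 0:
            raise ValueError("lesion semi-axes must be positive")

    @property
    def analytic_volume_ml(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass(frozen=True)
class ConfounderSpec:
    """Extratumoral hotspot: 'vascular_rim', 'pituitary' or 'skin'."""

    kind: str = "vascular_rim"
    intensity_ratio: float = 2.5

    def __post_init__(self) -> None:
        if self.kind not in ("vascular_rim", "pituitary", "skin"):
            raise ValueError(f"unknown confounder kind {self.kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic scan."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semi_axes_mm: tuple[float, float, float] = (70.0, 85.0, 65.0)
    background_mean: float = 1.0
    noise_sigma: float = 0.05       # fraction of background_mean
    psf_fwhm_mm: float = 5.0        # 0 disables blurring
    lesions: tuple[LesionSpec, ...] = (LesionSpec(),)
    confounders: tuple[ConfounderSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")
        if self.noise_sigma < 0 or self.psf_fwhm_mm < 0:
            raise ValueError("noise_sigma and psf_fwhm_mm must be >= 0")
        for les in self.lesions:
            # conservative inside-brain check: lesion bounding box per axis
            for c, s, a in zip(les.center_mm, les.semi_axes_mm,
                               self.brain_semi_axes_mm):
                if abs(c) + s > a:
                    raise ValueError(
                        f"lesion at {les.center_mm} with semi-axes "
                        f"{les.semi_axes_mm} extends outside the brain"
                    )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        sp = np.asarray(self.spacing_mm, float)
        aff[:3, :3] = np.diag(sp)
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * sp
        return aff


@dataclass
class StaticPhantom:
    image: ImageVolume
    lesion_masks: list[BinaryMask]
    brain_mask: BinaryMask
    confounder_mask: BinaryMask
    spec: PhantomSpec
    truth: dict

    @property
    def lesion_union(self) -> BinaryMask:
        if not self.lesion_masks:
            return BinaryMask(np.zeros(self.image.grid_shape, bool),
                              self.image.affine)
        data = np.logical_or.reduce([m.data for m in self.lesion_masks])
        return BinaryMask(data, self.image.affine)


@dataclass
class DynamicPhantom:
    series: DynamicSeries
    lesion_masks: list[BinaryMask]
    brain_mask: BinaryMask
    confounder_mask: BinaryMask
    spec: PhantomSpec
    truth: dict

    @property
    def lesion_union(self) -> BinaryMask:
        if not self.lesion_masks:
            return BinaryMask(np.zeros(self.series.grid_shape, bool),
                              self.series.affine)
        data = np.logical_or.reduce([m.data for m in self.lesion_masks])
        return BinaryMask(data, self.series.affine)


# ---------------------------------------------------------------------------
# Geometry helpers


def _world_grid(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    aff = spec.affine
    axes = [aff[i, i] * np.arange(spec.grid_shape[i]) + aff[i, 3]
            for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grid, center, semi_axes) -> np.ndarray:
    x, y, z = grid
    cx, cy, cz = center
    ax, ay, az = semi_axes
    rho2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return rho2 <= 1.0


def _brain_rho(grid, spec: PhantomSpec) -> np.ndarray:
    x, y, z = grid
    ax, ay, az = spec.brain_semi_axes_mm
    return np.sqrt((x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2)


def _confounder_mask(grid, spec: PhantomSpec, conf: ConfounderSpec) -> np.ndarray:
    rho = _brain_rho(grid, spec)
    z = grid[2]
    if conf.kind == "vascular_rim":
        # thin supra-tentorial rim just inside the brain surface
        return (rho >= 0.88) & (rho <= 1.0) & (z >= 0.5 * spec.brain_semi_axes_mm[2])
    if conf.kind == "pituitary":
        return _ellipsoid(grid, (0.0, 10.0, -0.7 * spec.brain_semi_axes_mm[2]),
                          (6.0, 6.0, 6.0))
    # skin: thin shell just outside the brain support
    return (rho > 1.02) & (rho <= 1.10)


def default_background_roi(spec: PhantomSpec, radius_mm: float = 12.0) -> BackgroundROI:
    """A spherical background ROI contralateral to the lesions.

    Mirrors the clinical practice of placing the ROI in healthy-appearing
    tissue in the hemisphere opposite the tumor.
    """
    if spec.lesions:
        mean_x = float(np.mean([l.center_mm[0] for l in spec.lesions]))
        side = -1.0 if mean_x >= 0 else 1.0
    else:
        side = -1.0
    center = (side * 0.55 * spec.brain_semi_axes_mm[0], 0.0, 0.0)
    return BackgroundROI.sphere(center, radius_mm)


# ---------------------------------------------------------------------------
# Generators


def _ideal_static(spec: PhantomSpec):
    """Pre-blur, pre-noise uptake plus all support masks."""
    grid = _world_grid(spec)
    brain = _brain_rho(grid, spec) <= 1.0
    uptake = np.where(brain, spec.background_mean, 0.0)
    lesion_masks = []
    for les in spec.lesions:
        m = _ellipsoid(grid, les.center_mm, les.semi_axes_mm)
        uptake[m] = les.tbr_true * spec.background_mean
        lesion_masks.append(m)
    conf_union = np.zeros(spec.grid_shape, dtype=bool)
    for conf in spec.confounders:
        m = _confounder_mask(grid, spec, conf)
        uptake[m] = conf.intensity_ratio * spec.background_mean
        conf_union |= m
    return uptake, brain, lesion_masks, conf_union


def _degrade(data: np.ndarray, spec: PhantomSpec,
             rng: np.random.Generator) -> np.ndarray:
    if spec.psf_fwhm_mm > 0:
        sigma_vox = (spec.psf_fwhm_mm / _FWHM_TO_SIGMA) / np.asarray(spec.spacing_mm)
        data = ndimage.gaussian_filter(data, sigma=sigma_vox)
    if spec.noise_sigma > 0:
        data = data + rng.normal(
            0.0, spec.noise_sigma * spec.background_mean, size=data.shape)
        data = np.clip(data, 0.0, None)
    return data


def _truth_manifest(spec: PhantomSpec, lesion_masks, affine) -> dict:
    vox_ml = float(abs(np.linalg.det(affine[:3, :3]))) / 1000.0
    lesions = []
    for les, m in zip(spec.lesions, lesion_masks):
        lesions.append({
            "center_mm": list(les.center_mm),
            "semi_axes_mm": list(les.semi_axes_mm),
            "tbr_true": les.tbr_true,
            "pattern": les.pattern,
            "true_btv_ml": float(m.sum()) * vox_ml,
            "analytic_volume_ml": les.analytic_volume_ml,
        })
    return {"background_mean": spec.background_mean, "lesions": lesions,
            "seed": spec.seed, "noise_sigma": spec.noise_sigma,
            "psf_fwhm_mm": spec.psf_fwhm_mm}


def generate_static(spec: PhantomSpec) -> StaticPhantom:
    """One static (late summed) phantom image with ground truth.

    Uptake is background inside the brain (zero outside) plus lesion and
    confounder plateaus, then PSF blur, then truncated Gaussian noise.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    uptake, brain, lesion_masks, conf = _ideal_static(spec)
    data = _degrade(uptake, spec, rng)
    aff = spec.affine
    return StaticPhantom(
        image=ImageVolume(data, aff),
        lesion_masks=[BinaryMask(m, aff) for m in lesion_masks],
        brain_mask=BinaryMask(brain, aff),
        confounder_mask=BinaryMask(conf, aff),
        spec=spec,
        truth=_truth_manifest(spec, lesion_masks, aff),
    )


_BACKGROUND_SHAPE = SaturatingUptake(30.0)   # mild pattern-I brain kinetics
_CONFOUNDER_SHAPE = RiseFall(3.0, 0.4)       # early vascular-like washout


def _window_norm(shape, timing: FrameTiming, window=(20.0, 40.0)) -> float:
    """Duration-weighted mean of the shape's frame averages in the window."""
    mids = timing.mid_times_min
    sel = (mids >= window[0]) & (mids <= window[1])
    avg = shape.frame_averages(timing)
    w = timing.duration_s[sel]
    return float((avg[sel] * w).sum() / w.sum())


def generate_dynamic(spec: PhantomSpec,
                     timing: FrameTiming | None = None) -> DynamicPhantom:
    """A 4D dynamic phantom whose late summed image matches the static one.

    Every region (background brain, each lesion, confounders) follows its
    kinetic shape, normalised so that the duration-weighted 20-40 min mean
    equals the region's static value; the 20-40 min summed image of the
    noise-free series therefore reproduces ``generate_static`` at matched
    parameters exactly.
    """
    if timing is None:
        timing = FrameTiming.uniform()
    end_min = float(timing.end_s[-1] / 60.0)
    rng = np.random.default_rng(spec.seed)
    uptake, brain, lesion_masks, conf = _ideal_static(spec)

    factors = np.ones((len(timing),) + tuple(spec.grid_shape))
    regions = [(brain, _BACKGROUND_SHAPE)]
    for les, m in zip(spec.lesions, lesion_masks):
        regions.append((m, shape_for_pattern(les.pattern, les.kinetic_params,
                                             end_min)))
    if conf.any():
        regions.append((conf, _CONFOUNDER_SHAPE))
    for mask, shape in regions:
        per_frame = shape.frame_averages(timing) / _window_norm(shape, timing)
        for t, f in enumerate(per_frame):
            factors[t][mask] = f

    aff = spec.affine
    frames = []
    for t in range(len(timing)):
        frames.append(ImageVolume(_degrade(uptake * factors[t], spec, rng), aff))
    series = DynamicSeries(frames, timing)
    return DynamicPhantom(
        series=series,
        lesion_masks=[BinaryMask(m, aff) for m in lesion_masks],
        brain_mask=BinaryMask(brain, aff),
        confounder_mask=BinaryMask(conf, aff),
        spec=spec,
        truth=_truth_manifest(spec, lesion_masks, aff),
    )


def sample_tac(pattern: str, timing: FrameTiming | None = None,
               params: dict | None = None, amplitude: float = 1.0,
               noise_sigma: float = 0.0,
               rng: np.random.Generator | None = None) -> TimeActivityCurve:
    """Draw one region-level TAC from a kinetic pattern generator.

    Frame values are the shape's exact frame averages scaled by
    ``amplitude``, with optional multiplicative Gaussian noise
    (``value * (1 + noise_sigma * Z)``), truncated at zero.
    """
    if timing is None:
        timing = FrameTiming.uniform()
    shape = shape_for_pattern(pattern, params, float(timing.end_s[-1] / 60.0))
    values = amplitude * shape.frame_averages(timing)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values * (1.0 + noise_sigma * rng.standard_normal(len(values)))
        values = np.clip(values, 0.0, None)
    return TimeActivityCurve(timing.mid_times_min, values, timing=timing)


def generate_longitudinal_cohort(n_patients: int = 10, n_timepoints: int = 3,
                                 volume_factor: float = 2.0,
                                 tbr_factor: float = 1.0,
                                 spec_template: PhantomSpec | None = None,
                                 seed: int = 0) -> list[dict]:
    """Simulated baseline + follow-up cohort with known per-scan truth.

    Each patient receives a randomized baseline lesion (location, size,
    TBR); at follow-up ``k`` the lesion's analytic volume is
    ``volume_factor**k`` x baseline (semi-axes scaled by the cube root) and
    its TBR is ``tbr_factor**k`` x baseline.  Three timepoints by default,
    matching the usual minimum for a longitudinal series.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if volume_factor <= 0 or tbr_factor <= 0:
        raise ValueError("change factors must be positive")
    if spec_template is None:
        spec_template = PhantomSpec()
    ss = np.random.SeedSequence(seed)
    patients = []
    ax, ay, az = spec_template.brain_semi_axes_mm
    for p, child in enumerate(ss.spawn(n_patients)):
        rng = np.random.default_rng(child)
        # lesion geometry scaled to the brain so the grown follow-up fits
        r0 = rng.uniform(0.11, 0.17) * min(ax, ay, az)
        center = (rng.uniform(0.35, 0.6) * ax * rng.choice([-1.0, 1.0]),
                  rng.uniform(-0.3, 0.3) * ay, rng.uniform(-0.23, 0.23) * az)
        tbr0 = rng.uniform(1.8, 2.5)
        scans = []
        for k in range(n_timepoints):
            scale = volume_factor ** (k / 3.0)  # cube-root per axis
            lesion = LesionSpec(
                center_mm=center,
                semi_axes_mm=(r0 * scale, r0 * scale, r0 * scale),
                tbr_true=tbr0 * tbr_factor ** k,
            )
            scan_seed = int(rng.integers(0, 2 ** 31 - 1))
            spec = replace(spec_template, lesions=(lesion,), seed=scan_seed)
            scans.append(generate_static(spec))
        patients.append({"patient_id": f"sim{p:03d}", "scans": scans})
    return patients
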