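"""Canonical FET time-activity shapes and their frame averages.

Two shape families cover the kinetic patterns used throughout the package:

* :class:`SaturatingUptake` — monotone wash-in ``1 - exp(-t/k)``; with no
  identifiable peak this is the canonical pattern-I curve.
* :class:`RiseFall` — piecewise-linear rise from zero to a peak at
  ``peak_min`` followed by a linear descent to ``end_fraction`` of the peak
  at the end of the acquisition; a late peak (>20 min) with a shallow
  descent is pattern II, an early peak (<20 min) with a pronounced descent
  is pattern III.

Shapes are dimensionless (peak amplitude 1) and evaluated either pointwise
or as exact per-frame time-averages against a :class:`~fetquant.io.FrameTiming`
schedule — a PET frame measures the mean activity over its interval, not an
instantaneous sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FrameTiming

__all__ = ["SaturatingUptake", "RiseFall", "shape_for_pattern",
           "DEFAULT_PATTERN_PARAMS"]


#: Default generator parameters per kinetic pattern (minutes / fractions).
DEFAULT_PATTERN_PARAMS = {
    "I": {"wash_in_min": 20.0},
    "II": {"peak_min": 25.0, "end_fraction": 0.93},
    "III": {"peak_min": 10.0, "end_fraction": 0.6},
}


@dataclass(frozen=True)
class SaturatingUptake:
    """Monotone wash-in curve ``s(t) = 1 - exp(-t / wash_in_min)``."""

    wash_in_min: float = 20.0

    def __post_init__(self) -> None:
        if self.wash_in_min <= 0:
            raise ValueError("wash_in_min must be positive")

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.asarray(t_min, float) / self.wash_in_min)

    def integral(self, a_min: float, b_min: float) -> float:
        k = self.wash_in_min
        return (b_min - a_min) + k * (np.exp(-b_min / k) - np.exp(-a_min / k))

    def frame_averages(self, timing: FrameTiming) -> np.ndarray:
        a = timing.start_s / 60.0
        b = timing.end_s / 60.0
        return np.array([self.integral(x, y) / (y - x) for x, y in zip(a, b)])


@dataclass(frozen=True)
class RiseFall:
    """Linear rise to a peak then linear descent to ``end_fraction`` x peak."""

    peak_min: float
    end_fraction: float
    end_min: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.peak_min < self.end_min:
            raise ValueError("peak_min must lie inside (0, end_min)")
        if not 0 <= self.end_fraction <= 1:
            raise ValueError("end_fraction must be in [0, 1]")

    def _breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([0.0, self.peak_min, self.end_min]),
                np.array([0.0, 1.0, self.end_fraction]))

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        ts, vs = self._breakpoints()
        return np.interp(np.asarray(t_min, float), ts, vs)

    def integral(self, a_min: float, b_min: float) -> float:
        # exact for a piecewise-linear shape: trapezoid over the knot union
        ts, vs = self._breakpoints()
        pts = np.unique(np.clip(np.r_[a_min, ts, b_min], a_min, b_min))
        return float(np.trapezoid(np.interp(pts, ts, vs), pts))

    def frame_averages(self, timing: FrameTiming) -> np.ndarray:
        a = timing.start_s / 60.0
        b = timing.end_s / 60.0
        return np.array([self.integral(x, y) / (y - x) for x, y in zip(a, b)])


def shape_for_pattern(pattern: str, params: dict | None = None,
                      end_min: float = 40.0):
    """Canonical shape for kinetic pattern 'I', 'II' or 'III'."""
    p = dict(DEFAULT_PATTERN_PARAMS[pattern])
    if params:
        p.update(params)
    if pattern == "I":
        return SaturatingUptake(p["wash_in_min"])
    return RiseFall(p["peak_min"], p["end_fraction"], end_min)
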