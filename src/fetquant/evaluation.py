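"""Segmentation and metric concordance evaluation.

Compares candidate delineations (e.g., from an external segmentation model)
against reference delineations: Dice similarity, voxel-level confusion
counts restricted to the brain+medulla domain, cohort summaries with
bootstrap confidence intervals, representative-case selection, scatter
concordance of clinical metrics, and longitudinal congruence of
baseline-to-follow-up changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import BinaryMask, require_grid_compatible
from .masking import DomainMask

__all__ = [
    "VoxelConfusion", "ConfusionMetrics", "ScanScore", "CohortSummary",
    "LongitudinalRecord", "dsc", "voxel_confusion", "confusion_metrics",
    "score_scan", "cohort_summary", "select_percentile_cases",
    "metric_concordance", "longitudinal_congruence",
]


def dsc(pred: BinaryMask, ref: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Convention: both masks empty -> 1.0 (nothing to find, nothing found);
    exactly one empty -> 0.0, the missed-lesion case.
    """
    require_grid_compatible(pred, ref, what="prediction and reference")
    a, b = pred.n_voxels, ref.n_voxels
    if a + b == 0:
        return 1.0
    inter = int(np.logical_and(pred.data, ref.data).sum())
    return 2.0 * inter / (a + b)


@dataclass
class VoxelConfusion:
    """TP/FP/FN/TN voxel counts within an evaluation domain."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "VoxelConfusion") -> "VoxelConfusion":
        return VoxelConfusion(self.tp + other.tp, self.fp + other.fp,
                              self.fn + other.fn, self.tn + other.tn)


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.sensitivity, self.specificity, self.ppv, self.npv)


def voxel_confusion(pred: BinaryMask, ref: BinaryMask,
                    domain: DomainMask) -> VoxelConfusion:
    """Voxel confusion counts over domain voxels only."""
    require_grid_compatible(pred, ref, what="prediction and reference")
    require_grid_compatible(pred, domain.mask, what="prediction and domain")
    d = domain.data
    p = pred.data[d]
    r = ref.data[d]
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = int(np.sum(~p & ~r))
    return VoxelConfusion(tp, fp, fn, tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(c: VoxelConfusion) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV, NPV; NaN where a denominator is zero."""
    return ConfusionMetrics(
        sensitivity=_safe_div(c.tp, c.tp + c.fn),
        specificity=_safe_div(c.tn, c.tn + c.fp),
        ppv=_safe_div(c.tp, c.tp + c.fp),
        npv=_safe_div(c.tn, c.tn + c.fn),
    )


@dataclass
class ScanScore:
    scan_id: str
    dsc: float
    confusion: VoxelConfusion | None = None
    detected: bool | None = None
    trivial: bool = False  # both masks empty: DSC=1 by convention


def score_scan(scan_id: str, pred: BinaryMask, ref: BinaryMask,
               domain: DomainMask, detection_threshold: float = 0.8) -> ScanScore:
    d = dsc(pred, ref)
    return ScanScore(
        scan_id=scan_id,
        dsc=d,
        confusion=voxel_confusion(pred, ref, domain),
        detected=d > detection_threshold,
        trivial=pred.is_empty() and ref.is_empty(),
    )


@dataclass
class CohortSummary:
    n_scans: int
    median_dsc: float
    median_dsc_ci: tuple[float, float]
    mean_dsc: float
    mean_dsc_ci: tuple[float, float]
    detection_rate: float
    detection_threshold: float
    pooled: ConfusionMetrics | None
    per_scan_mean: ConfusionMetrics | None
    per_scan_mean_ci: dict = field(default_factory=dict)


def _bootstrap_ci(values: np.ndarray, statistic, n_boot: int,
                  rng: np.random.Generator,
                  alpha: float = 0.05) -> tuple[float, float]:
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = statistic(values[idx], axis=1)
    lo, hi = np.nanpercentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def cohort_summary(scores: list[ScanScore], detection_threshold: float = 0.8,
                   n_boot: int = 10_000, seed: int | None = 0) -> CohortSummary:
    """Cohort-level DSC and confusion summaries.

    Confusion metrics are reported under BOTH aggregations — pooled (metrics
    of the summed counts) and per-scan averaged — because the two answer
    different questions and can differ materially when scan sizes vary.
    95% CIs come from a seedable nonparametric percentile bootstrap over
    scans.
    """
    if len(scores) == 0:
        raise ValueError("cohort_summary requires at least one scan")
    rng = np.random.default_rng(seed)
    d = np.array([s.dsc for s in scores])
    median_ci = _bootstrap_ci(d, np.median, n_boot, rng)
    mean_ci = _bootstrap_ci(d, np.mean, n_boot, rng)

    pooled = per_scan = None
    per_scan_ci: dict = {}
    confs = [s.confusion for s in scores if s.confusion is not None]
    if len(confs) == len(scores):
        total = confs[0]
        for c in confs[1:]:
            total = total + c
        pooled = confusion_metrics(total)
        per = np.array([confusion_metrics(c).as_tuple() for c in confs])
        means = np.nanmean(per, axis=0)
        per_scan = ConfusionMetrics(*[float(v) for v in means])
        names = ["sensitivity", "specificity", "ppv", "npv"]
        for j, name in enumerate(names):
            col = per[:, j]
            col = col[~np.isnan(col)]
            if len(col) > 0:
                per_scan_ci[name] = _bootstrap_ci(col, np.mean, n_boot, rng)

    return CohortSummary(
        n_scans=len(scores),
        median_dsc=float(np.median(d)),
        median_dsc_ci=median_ci,
        mean_dsc=float(np.mean(d)),
        mean_dsc_ci=mean_ci,
        detection_rate=float(np.mean(d > detection_threshold)),
        detection_threshold=detection_threshold,
        pooled=pooled,
        per_scan_mean=per_scan,
        per_scan_mean_ci=per_scan_ci,
    )


def select_percentile_cases(scores: list[ScanScore],
                            percentiles=(2, 50, 98)) -> list[str]:
    """Representative scans at the requested empirical DSC percentiles.

    Nearest-rank selection on the DSC-sorted cohort; ties broken by the
    lower original scan index.  The (2, 50, 98) defaults pick worst, median
    and best representative cases.
    """
    if len(scores) == 0:
        raise ValueError("select_percentile_cases requires at least one scan")
    order = sorted(range(len(scores)), key=lambda i: (scores[i].dsc, i))
    n = len(order)
    out = []
    for p in percentiles:
        rank = max(1, math.ceil(p / 100.0 * n))  # nearest-rank, 1-based
        out.append(scores[order[min(rank, n) - 1]].scan_id)
    return out


@dataclass
class ConcordanceResult:
    pearson_r: float
    slope: float
    intercept: float
    n_used: int
    n_dropped: int


def metric_concordance(pairs) -> ConcordanceResult:
    """Pearson correlation and least-squares line for method-A vs method-B.

    Incomplete (NaN) pairs are dropped pairwise and counted; at least three
    complete pairs are required.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) sequence")
    ok = ~np.isnan(arr).any(axis=1)
    dropped = int((~ok).sum())
    arr = arr[ok]
    if len(arr) < 3:
        raise ValueError("metric_concordance needs at least 3 complete pairs")
    fit = stats.linregress(arr[:, 0], arr[:, 1])
    return ConcordanceResult(pearson_r=float(fit.rvalue), slope=float(fit.slope),
                             intercept=float(fit.intercept),
                             n_used=len(arr), n_dropped=dropped)


@dataclass
class LongitudinalRecord:
    """Per-patient series of scan metrics under two delineation methods.

    ``method_a`` / ``method_b`` map metric name -> per-scan values in
    chronological order (index 0 is baseline).
    """

    patient_id: str
    method_a: dict[str, list[float]]
    method_b: dict[str, list[float]]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.method_a.values()}
        lengths |= {len(v) for v in self.method_b.values()}
        if len(lengths) != 1:
            raise ValueError("all metric series must have equal length")
        if set(self.method_a) != set(self.method_b):
            raise ValueError("both methods must report the same metrics")
        self.n_scans = lengths.pop()
        if self.n_scans < 2:
            raise ValueError("longitudinal analysis needs at least 2 scans")


def _delta_sign(delta: float, baseline: float, dead_zone: float) -> int:
    if abs(delta) <= dead_zone * abs(baseline):
        return 0
    return 1 if delta > 0 else -1


def longitudinal_congruence(record: LongitudinalRecord,
                            dead_zone: float = 0.05) -> dict:
    """Direction-of-change congruence between two methods.

    For each follow-up scan and metric, the change from baseline is computed
    for both methods; the interval is congruent when the signs agree, with
    changes smaller than ``dead_zone`` x baseline treated as "no change" on
    either side.  Returns per-metric lists of per-interval flags plus the
    deltas for audit.
    """
    out: dict = {"patient_id": record.patient_id, "metrics": {}}
    for name in record.method_a:
        a = np.asarray(record.method_a[name], float)
        b = np.asarray(record.method_b[name], float)
        flags, deltas = [], []
        for i in range(1, record.n_scans):
            da, db = a[i] - a[0], b[i] - b[0]
            sa = _delta_sign(da, a[0], dead_zone)
            sb = _delta_sign(db, b[0], dead_zone)
            flags.append(sa == sb)
            deltas.append({"delta_a": float(da), "delta_b": float(db),
                           "sign_a": sa, "sign_b": sb})
        out["metrics"][name] = {"congruent": flags, "deltas": deltas,
                                "all_congruent": all(flags)}
    out["all_congruent"] = all(m["all_congruent"] for m in out["metrics"].values())
    return out
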