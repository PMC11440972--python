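"""End-to-end orchestration with a single resolved configuration.

Every report embeds the resolved configuration (and its hash) so a result
can be re-executed from its own provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .delineation import BackgroundROI, delineate
from .dynamics import classify_pattern, extract_tac
from .evaluation import ScanScore, cohort_summary, metric_concordance, score_scan
from .io import BinaryMask, DynamicSeries, ImageVolume
from .masking import DomainMask
from .metrics import lesion_metrics

__all__ = ["PipelineConfig", "run_scan", "run_cohort"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, defaulting to the standard protocol."""

    threshold_ratio: float = 1.6
    min_ml: float = 0.1
    dilation_iterations: int = 20
    summed_window_min: tuple[float, float] = (20.0, 40.0)
    ttp_cutoff_min: float = 20.0
    increasing_tol: float = 0.05
    tac_smooth: bool = False
    classify_method: str = "fit"
    detection_threshold: float = 0.8
    bootstrap_resamples: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "summed_window_min" in d:
            d["summed_window_min"] = tuple(d["summed_window_min"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict:
    return {"config": config.to_dict(), "config_hash": config.config_hash,
            "fetquant_version": __version__}


def run_scan(image: ImageVolume, roi: BackgroundROI, domain: DomainMask,
             exclusions: list[BinaryMask] | None = None,
             series: DynamicSeries | None = None,
             config: PipelineConfig | None = None,
             scan_id: str = "scan") -> dict:
    """Delineate one scan and extract its clinical metrics (and TAC).

    Without a dynamic series the TAC section is reported as absent rather
    than failing: dynamic acquisition is optional in practice.
    """
    config = config or PipelineConfig()
    result = delineate(image, roi, domain, exclusions,
                       ratio=config.threshold_ratio, min_ml=config.min_ml)
    report: dict = {"scan_id": scan_id, **_provenance(config),
                    "delineation": result.report()}
    if result.btv_mask.is_empty():
        report["metrics"] = None
        report["tac"] = None
        return report

    scan_m, comp_m = lesion_metrics(image, result.btv_mask,
                                    result.background_mean, per_component=True)
    report["metrics"] = {
        "btv_ml": scan_m.btv_ml, "tbr_mean": scan_m.tbr_mean,
        "tbr_max": scan_m.tbr_max, "peak_location_mm": list(scan_m.peak_location_mm),
        "peak_ties": scan_m.peak_ties, "n_components": scan_m.n_components,
        "per_component": [
            {"btv_ml": c.btv_ml, "tbr_mean": c.tbr_mean, "tbr_max": c.tbr_max,
             "peak_location_mm": list(c.peak_location_mm)} for c in comp_m],
    }
    if series is None:
        report["tac"] = None
    else:
        tac = extract_tac(series, result.btv_mask)
        cls = classify_pattern(tac, cutoff_min=config.ttp_cutoff_min,
                               increasing_tol=config.increasing_tol,
                               smooth=config.tac_smooth,
                               method=config.classify_method)
        report["tac"] = {
            "mid_times_min": tac.mid_times_min.tolist(),
            "mean_uptake": tac.values.tolist(),
            "ttp_min": cls.ttp_min, "pattern": cls.pattern,
            "end_to_peak_ratio": cls.end_to_peak_ratio,
        }
    return report


def run_cohort(entries: list[dict], config: PipelineConfig | None = None) -> dict:
    """Evaluate a cohort of (prediction, reference) delineation pairs.

    Each entry needs ``scan_id``, ``pred`` (BinaryMask), ``ref``
    (BinaryMask) and ``domain`` (DomainMask); optional ``metrics_pred`` /
    ``metrics_ref`` dicts (metric name -> value) feed the concordance
    report.
    """
    config = config or PipelineConfig()
    if len(entries) == 0:
        raise ValueError("run_cohort requires at least one scan entry")
    scores: list[ScanScore] = []
    for e in entries:
        scores.append(score_scan(e["scan_id"], e["pred"], e["ref"], e["domain"],
                                 detection_threshold=config.detection_threshold))
    summary = cohort_summary(scores,
                             detection_threshold=config.detection_threshold,
                             n_boot=config.bootstrap_resamples,
                             seed=config.seed)
    report: dict = {
        **_provenance(config),
        "n_scans": summary.n_scans,
        "per_scan": [{"scan_id": s.scan_id, "dsc": s.dsc,
                      "detected": s.detected,
                      "confusion": asdict(s.confusion)} for s in scores],
        "summary": {
            "median_dsc": summary.median_dsc,
            "median_dsc_ci95": list(summary.median_dsc_ci),
            "mean_dsc": summary.mean_dsc,
            "mean_dsc_ci95": list(summary.mean_dsc_ci),
            "detection_rate": summary.detection_rate,
            "pooled": asdict(summary.pooled) if summary.pooled else None,
            "per_scan_mean": (asdict(summary.per_scan_mean)
                              if summary.per_scan_mean else None),
        },
    }
    with_metrics = [e for e in entries
                    if e.get("metrics_pred") and e.get("metrics_ref")]
    if len(with_metrics) >= 3:
        conc = {}
        for name in with_metrics[0]["metrics_pred"]:
            pairs = [(e["metrics_ref"][name], e["metrics_pred"][name])
                     for e in with_metrics]
            try:
                c = metric_concordance(pairs)
                conc[name] = {"pearson_r": c.pearson_r, "slope": c.slope,
                              "intercept": c.intercept, "n_used": c.n_used,
                              "n_dropped": c.n_dropped}
            except ValueError:
                conc[name] = None
        report["concordance"] = conc
    return report
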