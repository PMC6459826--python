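"""Detection-performance evaluation over a simulated ensemble.

Turns per-replicate composite series into the experiment's summaries:
true/false-positive proportions per metric and treatment, mean maximum
signal strength, consecutive-run statistics, lead-time distributions,
training-length sensitivity and ROC curves over a sigma-threshold sweep.

Recovery-treatment replicates are assessed between the release year and
their estimated recovery point; control replicates over the 50-year window
after the nominal release year.  Treatment labels (not the breakpoint
margin rule) decide whether a replicate counts toward TP or FP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .breakpoint import recovery_time
from .ewsr import (CompositeMetric, DetectionConfig, compute_composites,
                   consecutive_filter, detect_signals, max_consecutive_run,
                   max_signal_strength)
from .simulator import AnnualSeries

__all__ = [
    "ReplicateResult", "ROCCurve", "analyze_ensemble", "classify_replicate",
    "summarize_ensemble", "roc_curve", "training_length_sweep",
]

Ensemble = Iterable[tuple[float, int, AnnualSeries]]


@dataclass
class ReplicateResult:
    """Detections of one metric on one replicate."""

    treatment: float
    replicate: int
    metric_name: str
    recovery_year: int | None
    recovered: bool
    assessment_window: tuple[int, int] | None
    signal_years: np.ndarray        # single-signal rule
    detection_years: np.ndarray     # k-consecutive rule
    max_strength: float
    max_run: int
    composite: CompositeMetric

    def detections(self, rule: str) -> np.ndarray:
        if rule == "single":
            return self.signal_years
        if rule == "consecutive":
            return self.detection_years
        raise ValueError(f"unknown rule {rule!r}")


@dataclass
class ROCCurve:
    metric_name: str
    rule: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"metric": self.metric_name, "rule": self.rule,
                             "threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def _windows_for(treatment: float, recovery_year: int | None,
                 release_start: int, control_end: int,
                 end_year: int) -> tuple[tuple[int, int] | None, bool]:
    if treatment == 0.0:
        return (release_start, control_end), False
    if recovery_year is None:
        return None, False
    return (release_start, recovery_year), True


def analyze_ensemble(ensemble: Ensemble,
                     metrics: Sequence[Sequence[str]] | None = None,
                     analysis_start_year: int = 2010,
                     release_start: int = 2040,
                     control_end: int = 2090,
                     threshold_sigma: float = 2.0,
                     consecutive_k: int = 2,
                     fit_start_year: int | None = None,
                     ) -> list[ReplicateResult]:
    """Full per-replicate analysis: indicators, composites, breakpoint,
    detection.

    For every replicate the recovery year is estimated by the
    single-breakpoint fit from the release year; composites use an
    expanding-window analysis from ``analysis_start_year`` with the
    training window ending the year before release.  Returns one
    :class:`ReplicateResult` per (replicate, metric).
    """
    if fit_start_year is None:
        fit_start_year = release_start
    results: list[ReplicateResult] = []
    for rate, rep, series in ensemble:
        recov = (recovery_time(series, fit_start_year=fit_start_year)
                 if rate != 0.0 else None)
        window, recovered = _windows_for(rate, recov, release_start,
                                         control_end, int(series.years[-1]))
        composites = compute_composites(series, analysis_start_year, metrics)
        for name, comp in composites.items():
            if window is None:
                results.append(ReplicateResult(
                    rate, rep, name, None, False, None,
                    np.empty(0, int), np.empty(0, int),
                    float("nan"), 0, comp))
                continue
            cfg = DetectionConfig(
                threshold_sigma=threshold_sigma,
                consecutive_k=consecutive_k,
                training_window=(analysis_start_year, release_start - 1),
                assessment_window=window)
            sig = detect_signals(comp, cfg)
            det = consecutive_filter(sig, consecutive_k)
            results.append(ReplicateResult(
                rate, rep, name, recov, recovered, window, sig, det,
                max_signal_strength(comp, window),
                max_consecutive_run(sig), comp))
    return results


def classify_replicate(result: ReplicateResult, rule: str) -> str | None:
    """TP/FN for recovery treatments, FP/TN for the control.

    Returns None for a recovery-treatment replicate with no estimated
    recovery point (excluded from denominators).
    """
    dets = result.detections(rule)
    if result.treatment == 0.0:
        return "FP" if dets.size else "TN"
    if not result.recovered:
        return None
    return "TP" if dets.size else "FN"


def _lead_times(result: ReplicateResult, rule: str) -> int | None:
    dets = result.detections(rule)
    if result.recovery_year is None or dets.size == 0:
        return None
    return int(result.recovery_year - dets.min())


def summarize_ensemble(results: Sequence[ReplicateResult],
                       rule: str = "single") -> pd.DataFrame:
    """Per (metric, treatment): proportion flagged, mean +/- SE of max
    strength, mean longest consecutive run, lead times.

    The proportion is TP/(TP+FN) in recovery treatments and FP/(FP+TN) in
    the control; SE is the sample SD over replicates / sqrt(n).
    """
    rows = []
    key = lambda r: (r.metric_name, r.treatment)
    groups: dict[tuple, list[ReplicateResult]] = {}
    for r in results:
        groups.setdefault(key(r), []).append(r)
    for (metric, treatment), grp in sorted(groups.items()):
        outcomes = [classify_replicate(r, rule) for r in grp]
        used = [(r, o) for r, o in zip(grp, outcomes) if o is not None]
        n = len(used)
        flagged = sum(o in ("TP", "FP") for _, o in used)
        strengths = np.array([r.max_strength for r, _ in used])
        strengths = strengths[np.isfinite(strengths)]
        runs = np.array([r.max_run for r, _ in used])
        leads = [lt for r, _ in used
                 if (lt := _lead_times(r, rule)) is not None]
        rows.append({
            "metric": metric, "treatment": treatment, "rule": rule,
            "n": n, "n_excluded": len(grp) - n,
            "proportion": flagged / n if n else float("nan"),
            "mean_max_strength": strengths.mean() if strengths.size else float("nan"),
            "se_max_strength": (strengths.std(ddof=1) / np.sqrt(strengths.size)
                                if strengths.size > 1 else float("nan")),
            "mean_max_run": runs.mean() if runs.size else float("nan"),
            "lead_times": leads,
        })
    return pd.DataFrame(rows)


def _reclassify(result: ReplicateResult, threshold: float,
                rule: str, k: int = 2) -> str | None:
    """Re-detect at an arbitrary threshold from the stored composite."""
    if result.assessment_window is None:
        return None
    lo, hi = result.assessment_window
    comp = result.composite
    m = (comp.years >= lo) & (comp.years <= hi)
    with np.errstate(invalid="ignore"):
        sig = comp.years[m & (comp.values > threshold)]
    dets = sig if rule == "single" else consecutive_filter(sig, k)
    if result.treatment == 0.0:
        return "FP" if dets.size else "TN"
    return "TP" if dets.size else "FN"


def default_thresholds() -> np.ndarray:
    """Sigma thresholds 0.01 to 6 (0.25 steps plus the endpoints and 2.0)."""
    t = np.concatenate([[0.01], np.arange(0.25, 6.0, 0.25), [6.0]])
    return np.unique(np.round(t, 6))


def roc_curve(results: Sequence[ReplicateResult], metric_name: str,
              rule: str = "single",
              thresholds: np.ndarray | None = None,
              consecutive_k: int = 2,
              per_treatment: bool = False) -> ROCCurve | pd.DataFrame:
    """ROC over a sigma-threshold sweep for one metric.

    TPR pools all recovery treatments; FPR is the control FP proportion.
    The default threshold grid spans 0.01-6 sigma and contains 2.0, the
    operating point of the main analysis.  ``per_treatment=True`` returns a
    tidy frame of one curve per decline rate instead.
    """
    if thresholds is None:
        thresholds = default_thresholds()
    sel = [r for r in results if r.metric_name == metric_name]
    if not any(r.treatment == 0.0 for r in sel):
        raise ValueError("ensemble has no control treatment")
    if not any(r.treatment != 0.0 for r in sel):
        raise ValueError("ensemble has no recovery treatment")

    def rates(subset):
        fpr, tpr = [], []
        for th in thresholds:
            out = [_reclassify(r, th, rule, consecutive_k) for r in subset]
            tp = out.count("TP"); fn = out.count("FN")
            fp = out.count("FP"); tn = out.count("TN")
            tpr.append(tp / (tp + fn) if tp + fn else float("nan"))
            fpr.append(fp / (fp + tn) if fp + tn else float("nan"))
        return np.asarray(fpr), np.asarray(tpr)

    if not per_treatment:
        fpr, tpr = rates(sel)
        return ROCCurve(metric_name, rule, np.asarray(thresholds), fpr, tpr)
    frames = []
    control = [r for r in sel if r.treatment == 0.0]
    for rate in sorted({r.treatment for r in sel if r.treatment != 0.0}):
        grp = [r for r in sel if r.treatment == rate] + control
        fpr, tpr = rates(grp)
        df = ROCCurve(metric_name, rule, np.asarray(thresholds), fpr,
                      tpr).to_frame()
        df["treatment"] = rate
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def training_length_sweep(ensemble: Ensemble, metric_name: str,
                          lengths: Sequence[int] = tuple(range(2, 31)),
                          release_start: int = 2040,
                          control_end: int = 2090,
                          threshold_sigma: float = 2.0,
                          consecutive_k: int = 2) -> pd.DataFrame:
    """TP/FP proportions as a function of training-window length.

    For each length L the analysis start is moved so exactly L training
    years precede the release year, and the whole pipeline (indicators,
    normalisation, detection, classification) is recomputed.  L=2 is the
    minimum needed by the running normalisation.
    """
    lengths = list(lengths)
    if any(L < 2 for L in lengths):
        raise ValueError("training length must be >= 2 years")
    ensemble = list(ensemble)
    members = None
    from .ewsr import enumerate_metric_combinations, metric_name as mname
    for m in enumerate_metric_combinations():
        if mname(m) == metric_name:
            members = m
    if members is None:
        raise ValueError(f"unknown metric {metric_name!r}")
    rows = []
    for L in lengths:
        start = release_start - L
        results = analyze_ensemble(
            ensemble, metrics=[members], analysis_start_year=start,
            release_start=release_start, control_end=control_end,
            threshold_sigma=threshold_sigma, consecutive_k=consecutive_k)
        for rule in ("single", "consecutive"):
            out = [classify_replicate(r, rule) for r in results]
            tp = out.count("TP"); fn = out.count("FN")
            fp = out.count("FP"); tn = out.count("TN")
            rows.append({
                "length": L, "rule": rule,
                "tp_proportion": tp / (tp + fn) if tp + fn else float("nan"),
                "fp_proportion": fp / (fp + tn) if fp + tn else float("nan"),
            })
    return pd.DataFrame(rows)
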