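"""Running normalisation, composite metrics and sigma-threshold detection.

Each raw indicator series w is normalised against its own running baseline:

    w_hat_t = (w_t - mean(w_1..w_t)) / sd(w_1..w_t),   t >= 2,

with the sample (n-1) SD and the current value included in both running
statistics.  Normalised indicators are summed over every non-empty subset
of the four (15 composite metrics).  A warning signal of recovery is
present in year t when the composite exceeds the sigma threshold (default
2); detections may additionally require k consecutive signal years.
Signals inside the training window are disregarded, although training data
feed all running statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .indicators import INDICATOR_IDS, IndicatorSeries, compute_indicator_series
from .simulator import AnnualSeries

__all__ = [
    "NormalizedSeries", "CompositeMetric", "DetectionConfig",
    "normalize_running", "enumerate_metric_combinations", "metric_name",
    "composite_metric", "compute_composites", "detect_signals",
    "consecutive_filter", "max_signal_strength", "max_consecutive_run",
]

_DISPLAY = {"AR1": "AR(1)", "CV": "CV",
            "MEAN_SIZE": "mean size", "SD_SIZE": "SD size"}


@dataclass
class NormalizedSeries:
    """Running-normalised values w_hat_t of one indicator (NaN where
    undefined, 0 where the running SD degenerates to 0)."""

    indicator_id: str
    years: np.ndarray
    values: np.ndarray
    degenerate: np.ndarray = field(default=None)  # True where running SD was 0


@dataclass
class CompositeMetric:
    """A subset of indicators and the per-year sum of their normalised
    values."""

    members: tuple[str, ...]
    years: np.ndarray
    values: np.ndarray

    @property
    def name(self) -> str:
        return metric_name(self.members)


@dataclass(frozen=True)
class DetectionConfig:
    """Threshold, consecutive-year rule and analysis windows.

    ``training_window`` seeds the running baseline but its exceedances are
    disregarded; only ``assessment_window`` years can yield signals.  With
    ``rescale_by_sqrt_k`` the threshold is multiplied by sqrt(#members)
    under an independence assumption (off by default: the composite sum is
    compared to the plain sigma threshold however many indicators it
    contains).
    """

    threshold_sigma: float = 2.0
    consecutive_k: int = 2
    training_window: tuple[int, int] = (2010, 2039)
    assessment_window: tuple[int, int] = (2040, 2090)
    rescale_by_sqrt_k: bool = False

    def __post_init__(self):
        if self.threshold_sigma <= 0:
            raise ValueError("threshold_sigma must be positive")
        if self.training_window[1] >= self.assessment_window[0]:
            raise ValueError("training window must precede assessment window")

    def threshold_for(self, n_members: int) -> float:
        if self.rescale_by_sqrt_k:
            return self.threshold_sigma * np.sqrt(n_members)
        return self.threshold_sigma


def normalize_running(raw: IndicatorSeries) -> NormalizedSeries:
    """Apply the running z-score to a raw indicator series.

    Running mean and SD run over the defined (non-NaN) values from the first
    defined year up to and including year t; w_hat is NaN until at least two
    defined values exist and 0 (flagged) where the running SD is 0.
    """
    vals = np.asarray(raw.values, dtype=float)
    out = np.full(vals.size, np.nan)
    degenerate = np.zeros(vals.size, dtype=bool)
    seen: list[float] = []
    for t, v in enumerate(vals):
        if not np.isfinite(v):
            continue
        seen.append(v)
        if len(seen) < 2:
            continue
        arr = np.asarray(seen)
        sd = arr.std(ddof=1)
        if sd == 0.0:
            out[t] = 0.0
            degenerate[t] = True
        else:
            out[t] = (v - arr.mean()) / sd
    return NormalizedSeries(indicator_id=raw.indicator_id,
                            years=np.asarray(raw.years), values=out,
                            degenerate=degenerate)


def enumerate_metric_combinations(
        indicator_ids: Sequence[str] = INDICATOR_IDS) -> list[tuple[str, ...]]:
    """All non-empty subsets of the indicators, by size then lexicographic.

    Four indicators give the 15 composite metrics evaluated throughout.
    """
    ids = list(dict.fromkeys(indicator_ids))
    if not ids:
        raise ValueError("need at least one indicator id")
    canonical = [i for i in INDICATOR_IDS if i in ids]
    canonical += [i for i in ids if i not in canonical]
    subsets: list[tuple[str, ...]] = []
    for size in range(1, len(canonical) + 1):
        subsets.extend(sorted(combinations(canonical, size)))
    return subsets


def metric_name(members: Sequence[str]) -> str:
    """Display name, e.g. ('AR1', 'SD_SIZE') -> 'AR(1) + SD size'."""
    ordered = [m for m in INDICATOR_IDS if m in members]
    return " + ".join(_DISPLAY.get(m, m) for m in ordered)


def composite_metric(members: Sequence[NormalizedSeries]) -> CompositeMetric:
    """Per-year sum of the members' normalised values.

    All members must share the year axis; a missing (NaN) member value makes
    the composite missing for that year.
    """
    if not members:
        raise ValueError("composite needs at least one member")
    years = np.asarray(members[0].years)
    for m in members[1:]:
        if not np.array_equal(np.asarray(m.years), years):
            raise ValueError("member year axes differ")
    stacked = np.vstack([m.values for m in members])
    values = stacked.sum(axis=0)  # NaN propagates
    ids = tuple(m.indicator_id for m in members)
    return CompositeMetric(members=ids, years=years, values=values)


def compute_composites(series: AnnualSeries, analysis_start_year: int,
                       metrics: Iterable[Sequence[str]] | None = None,
                       window_scheme: str = "expanding",
                       window: int | None = None,
                       ) -> dict[str, CompositeMetric]:
    """Raw indicators -> normalisation -> all requested composites.

    Convenience pipeline for one annual series; ``metrics`` defaults to all
    15 subsets of the four indicators.  Returns a dict keyed by display
    name.
    """
    if metrics is None:
        metrics = enumerate_metric_combinations()
    needed = sorted({i for m in metrics for i in m})
    normalized = {
        i: normalize_running(compute_indicator_series(
            series, i, analysis_start_year, window_scheme, window))
        for i in needed
    }
    out = {}
    for members in metrics:
        comp = composite_metric([normalized[i] for i in members])
        out[comp.name] = comp
    return out


def detect_signals(metric: CompositeMetric,
                   cfg: DetectionConfig) -> np.ndarray:
    """Assessment-window years where the composite exceeds the threshold.

    Training-window exceedances are excluded (the training data already
    participated in the running statistics upstream).
    """
    lo, hi = cfg.assessment_window
    threshold = cfg.threshold_for(len(metric.members))
    in_window = (metric.years >= lo) & (metric.years <= hi)
    with np.errstate(invalid="ignore"):
        over = metric.values > threshold
    return metric.years[in_window & over]


def consecutive_filter(signal_years, k: int = 2) -> np.ndarray:
    """Years ending a run of at least k consecutive signal years (k=1:
    identity)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    years = np.asarray(sorted(set(np.asarray(signal_years, dtype=int).tolist())))
    if k == 1 or years.size == 0:
        return years
    yearset = set(years.tolist())
    keep = [y for y in years
            if all((y - j) in yearset for j in range(k))]
    return np.asarray(keep, dtype=int)


def max_signal_strength(metric: CompositeMetric,
                        window: tuple[int, int]) -> float:
    """Maximum composite value over [window[0], window[1]] (NaN skipped;
    NaN if every value in the window is missing or the window is empty)."""
    lo, hi = window
    m = (metric.years >= lo) & (metric.years <= hi)
    vals = metric.values[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.max())


def max_consecutive_run(signal_years) -> int:
    """Length of the longest run of consecutive years in the set (0 if
    empty)."""
    years = sorted(set(np.asarray(signal_years, dtype=int).tolist()))
    if not years:
        return 0
    best = run = 1
    for a, b in zip(years, years[1:]):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return best
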