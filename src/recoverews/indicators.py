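"""Raw stability indicators computed per year from an annual series.

Two abundance-based indicators rooted in critical slowing down — the
coefficient of variation (CV, a noise statistic) and the lag-1
autoregressive coefficient (AR(1), a memory statistic) of the biomass
series — and two trait-based indicators, the yearly mean and standard
deviation of observable body size.  All four are expected to rise before
the recovery of a collapsed, size-structured stock.

CV and AR(1) are computed over a window of biomass values ending at the
focal year; the default scheme is an expanding window from the analysis
start year (the running-baseline normalisation downstream makes this the
natural companion), with a trailing rolling window available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import AnnualSeries

__all__ = [
    "INDICATOR_IDS", "IndicatorSeries", "InsufficientDataError",
    "UndefinedValueError", "coefficient_of_variation", "ar1_coefficient",
    "compute_indicator_series",
]

#: canonical order of the four indicators
INDICATOR_IDS: tuple[str, ...] = ("AR1", "CV", "MEAN_SIZE", "SD_SIZE")


class InsufficientDataError(ValueError):
    """Too few observations to compute the statistic."""


class UndefinedValueError(ValueError):
    """The statistic is mathematically undefined for this input."""


@dataclass
class IndicatorSeries:
    """Raw values w_t of one indicator on the analysis-year axis (NaN where
    undefined)."""

    indicator_id: str
    years: np.ndarray
    values: np.ndarray
    window_scheme: str = "expanding"


def coefficient_of_variation(x) -> float:
    """Sample SD (n-1 denominator) divided by the mean.

    Raises :class:`InsufficientDataError` for fewer than 2 values and
    :class:`UndefinedValueError` when the mean is zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"CV needs at least 2 values, got {x.size}")
    m = x.mean()
    if m == 0.0:
        raise UndefinedValueError("CV undefined: mean is zero")
    return float(x.std(ddof=1) / m)


def ar1_coefficient(x) -> float:
    """Lag-1 autoregressive coefficient by OLS with intercept.

    The slope of the least-squares regression of x_t on x_{t-1}; not
    clamped to [-1, 1].  A constant window (zero predictor variance) is
    degenerate and returns 0.0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(
            f"AR(1) needs at least 3 values, got {x.size}")
    lagged, current = x[:-1], x[1:]
    var = lagged.var()
    if var == 0.0:
        return 0.0
    cov = np.mean((lagged - lagged.mean()) * (current - current.mean()))
    return float(cov / var)


def _windows(n: int, scheme: str, k: int | None):
    """Yield (t, start) index pairs for window [start, t] at each position t."""
    if scheme == "expanding":
        for t in range(n):
            yield t, 0
    elif scheme == "rolling":
        if k is None or k < 2:
            raise ValueError("rolling scheme needs window k >= 2")
        for t in range(n):
            yield t, max(0, t - k + 1)
    else:
        raise ValueError(f"unknown window scheme {scheme!r}")


def compute_indicator_series(series: AnnualSeries, indicator_id: str,
                             analysis_start_year: int,
                             window_scheme: str = "expanding",
                             window: int | None = None) -> IndicatorSeries:
    """Raw indicator values per analysis year.

    CV and AR(1) are computed on biomass over the window ending at year t
    (values at years before the window reaches the minimum length are NaN:
    the first defined year is analysis_start+1 for CV and analysis_start+2
    for AR(1) under the expanding scheme).  MEAN_SIZE and SD_SIZE are the
    year-t survey observations themselves; missing observations propagate
    as NaN.
    """
    if indicator_id not in INDICATOR_IDS:
        raise ValueError(f"unknown indicator {indicator_id!r}")
    mask = series.years >= analysis_start_year
    years = series.years[mask]
    if years.size == 0:
        raise InsufficientDataError(
            f"series has no years >= {analysis_start_year}")

    if indicator_id == "MEAN_SIZE":
        vals = series.mean_size[mask].astype(float)
    elif indicator_id == "SD_SIZE":
        vals = series.sd_size[mask].astype(float)
    else:
        biomass = series.biomass[mask].astype(float)
        n = biomass.size
        vals = np.full(n, np.nan)
        min_len = 2 if indicator_id == "CV" else 3
        for t, start in _windows(n, window_scheme, window):
            w = biomass[start:t + 1]
            if w.size < min_len:
                continue
            if indicator_id == "CV":
                try:
                    vals[t] = coefficient_of_variation(w)
                except UndefinedValueError:
                    vals[t] = np.nan
            else:
                vals[t] = ar1_coefficient(w)
    scheme = window_scheme if window is None else f"rolling({window})"
    return IndicatorSeries(indicator_id=indicator_id, years=years,
                           values=vals, window_scheme=scheme)
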