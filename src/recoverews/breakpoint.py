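"""Recovery-time estimation by single-breakpoint piecewise-constant fitting.

The recovery point of a released population is the breakpoint of the
best-fitting (least squares) piecewise-constant model with one break,
fitted to the post-release biomass series: an exhaustive search over all
admissible break positions, each segment fitted by its mean.  Ties are
broken toward the earliest break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import AnnualSeries

__all__ = ["BreakpointFit", "fit_piecewise_constant", "recovery_time"]


class InsufficientDataError(ValueError):
    pass


@dataclass
class BreakpointFit:
    """Result of the exhaustive single-break search.

    ``break_index`` is the 0-based index of the first element of the second
    segment; ``seg_means`` the two segment means; ``sse`` the total sum of
    squared errors; ``tie`` flags multiple SSE-optimal breaks (the earliest
    is returned); ``candidates`` the admissible break indices searched.
    """

    break_index: int
    seg_means: tuple[float, float]
    sse: float
    tie: bool
    candidates: np.ndarray


def fit_piecewise_constant(y, min_segment: int = 2) -> BreakpointFit:
    """Globally optimal single-break piecewise-constant fit to ``y``.

    Every break position leaving at least ``min_segment`` points in each
    segment is evaluated; segments are fitted by their means and the break
    minimising total SSE is returned (earliest on ties).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if min_segment < 1:
        raise ValueError("min_segment must be >= 1")
    if n < 2 * min_segment:
        raise InsufficientDataError(
            f"need at least {2 * min_segment} points, got {n}")
    candidates = np.arange(min_segment, n - min_segment + 1)
    # prefix sums give each segment's SSE in O(1)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_sse(a: int, b: int) -> float:  # [a, b)
        m = b - a
        s, ss = c1[b] - c1[a], c2[b] - c2[a]
        return ss - s * s / m

    sses = np.array([seg_sse(0, k) + seg_sse(k, n) for k in candidates])
    best = float(sses.min())
    optimal = candidates[np.isclose(sses, best, rtol=0.0, atol=1e-9 * max(1.0, abs(best)))]
    k = int(optimal[0])
    means = (float(y[:k].mean()), float(y[k:].mean()))
    return BreakpointFit(break_index=k, seg_means=means, sse=best,
                         tie=optimal.size > 1, candidates=candidates)


def recovery_time(series: AnnualSeries, fit_start_year: int = 2040,
                  min_segment: int = 2,
                  margin: float = 0.10) -> int | None:
    """Estimated recovery year of a replicate, or None if not recovered.

    Fits the single-break model to biomass from ``fit_start_year`` to the
    series end and returns the first year of the upper segment.  The
    replicate counts as non-recovered (None) when the second-segment mean
    does not exceed the first by the relative ``margin`` — a classification
    convenience; treatment labels, not this rule, drive TP/FP accounting.
    """
    mask = series.years >= fit_start_year
    y = series.biomass[mask]
    years = series.years[mask]
    fit = fit_piecewise_constant(y, min_segment=min_segment)
    lo, hi = fit.seg_means
    if not (hi > lo * (1.0 + margin)):
        return None
    return int(years[fit.break_index])
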