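"""Logarithmic body-mass grid for the size-spectrum simulator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SizeGrid:
    """Log-spaced discretisation of body mass.

    ``centers`` are the class representative masses (grams), strictly
    increasing with a constant ratio between neighbours.  ``widths`` are the
    per-class mass widths obtained from geometric class edges, so that
    ``sum(N * widths)`` integrates an abundance density (individuals per
    gram) to a head count.
    """

    centers: np.ndarray
    widths: np.ndarray
    ratio: float = field(default=0.0)

    @property
    def n_classes(self) -> int:
        return self.centers.size

    @property
    def w_min(self) -> float:
        return float(self.centers[0])

    @property
    def w_max(self) -> float:
        return float(self.centers[-1])


def build_size_grid(n_classes: int = 100, w_min: float = 0.001,
                    w_max: float = 4.0e4) -> SizeGrid:
    """Build a log-spaced mass grid with ``n_classes`` centers on [w_min, w_max].

    Class edges sit at the geometric means of neighbouring centers (the outer
    edges are extrapolated by the same ratio), so every class has width
    ``w * (sqrt(r) - 1/sqrt(r))`` where ``r`` is the common center ratio.

    Raises
    ------
    ValueError
        If ``n_classes < 2`` or the mass bounds are not ``0 < w_min < w_max``.
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    if not (0.0 < w_min < w_max):
        raise ValueError(f"need 0 < w_min < w_max, got ({w_min}, {w_max})")
    centers = np.geomspace(w_min, w_max, n_classes)
    ratio = (w_max / w_min) ** (1.0 / (n_classes - 1))
    half = np.sqrt(ratio)
    widths = centers * (half - 1.0 / half)
    return SizeGrid(centers=centers, widths=widths, ratio=ratio)
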