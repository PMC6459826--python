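"""Fishing-mortality schedules: burn-in, historic ramp, plateau, linear release.

A schedule maps calendar year to an instantaneous fishing mortality rate
F (per year) applied above the gear-selectivity mass.  The experiment
phases are:

* burn-in (default 1667-1966): unfished, the spectrum equilibrates;
* historic (1967-2009): F ramps linearly up to the plateau level,
  standing in for the recorded rise of exploitation;
* plateau / collapse period (2010-2039): F held at ``plateau_F``;
* release (2040 onward): F declines linearly at ``decline_rate`` of the
  plateau level per year until it reaches exactly 0, or stays at the
  plateau level forever for the control (``decline_rate = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FishingSchedule:
    plateau_F: float
    decline_rate: float
    burn_in_start: int = 1667
    historic_start: int = 1967
    plateau_start: int = 2010
    release_start: int = 2040
    end_year: int = 2200
    # F at the start of the historic ramp, as a fraction of plateau_F
    historic_initial_fraction: float = 0.25

    def F(self, year) -> np.ndarray | float:
        """Fishing mortality (per year) in calendar year ``year``.

        Accepts scalars or arrays of years.
        """
        t = np.asarray(year, dtype=float)
        f = np.zeros_like(t)
        ramp = (t >= self.historic_start) & (t < self.plateau_start)
        frac = self.historic_initial_fraction
        span = self.plateau_start - self.historic_start
        f = np.where(
            ramp,
            self.plateau_F * (frac + (1 - frac) * (t - self.historic_start) / span),
            f,
        )
        plateau = (t >= self.plateau_start) & (t < self.release_start)
        f = np.where(plateau, self.plateau_F, f)
        release = t >= self.release_start
        decline = self.plateau_F * np.maximum(
            0.0, 1.0 - self.decline_rate * (t - self.release_start)
        )
        f = np.where(release, decline, f)
        if np.isscalar(year):
            return float(f)
        return f

    @property
    def is_control(self) -> bool:
        return self.decline_rate == 0.0

    def years(self) -> np.ndarray:
        return np.arange(self.burn_in_start, self.end_year + 1)


def make_fishing_schedule(plateau_F: float, decline_rate: float,
                          **phase_years) -> FishingSchedule:
    """Construct a :class:`FishingSchedule`.

    ``decline_rate`` is the fraction of the plateau F removed per year after
    the release year; 0 gives the constant-pressure control.  Phase years
    (``burn_in_start``, ``historic_start``, ``plateau_start``,
    ``release_start``, ``end_year``) may be overridden by keyword.
    """
    if plateau_F < 0:
        raise ValueError(f"plateau_F must be >= 0, got {plateau_F}")
    if not (0.0 <= decline_rate <= 1.0):
        raise ValueError(f"decline_rate must be in [0, 1], got {decline_rate}")
    return FishingSchedule(plateau_F=plateau_F, decline_rate=decline_rate,
                           **phase_years)
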