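"""Estimate recovery years by single-breakpoint fitting.

Fits a piecewise-constant model with one break to the post-release biomass
of replicates at two release rates; the break year is the estimated
recovery point.  A control replicate yields no recovery.
"""

import numpy as np

from recoverews import (FishingSchedule, SpeciesParams, build_size_grid,
                        recovery_time, run_simulation)
from recoverews.breakpoint import fit_piecewise_constant

params = SpeciesParams()
grid = build_size_grid()

for rate, label in [(0.10, "10 %/yr release"), (0.02, "2 %/yr release"),
                    (0.0, "control")]:
    schedule = FishingSchedule(plateau_F=0.6, decline_rate=rate)
    series = run_simulation(params, schedule, grid, seed=1, burn_in="fast")
    year = recovery_time(series, fit_start_year=2040)
    if year is None:
        print(f"{label:>16}: no recovery detected (margin rule)")
        continue
    mask = series.years >= 2040
    fit = fit_piecewise_constant(series.biomass[mask])
    lo, hi = fit.seg_means
    print(f"{label:>16}: recovery year {year}  "
          f"(segment means {lo/1e9:.1f} -> {hi/1e9:.1f} kt)")

print("\nFaster releases recover earlier; the exhaustive least-squares "
      "search returns\nthe first year of the upper segment, the reference "
      "point against which warning-\nsignal lead times are measured.")
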