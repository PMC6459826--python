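"""Simulate one collapse-and-release replicate and print its trajectory.

Runs the surrogate size-spectrum model under the 10 %/yr release schedule
(fishing drops linearly to zero over 2040-2050) and shows annual biomass,
mean body size and SD body size of observable (>10 g) individuals: the
collapse plateau, the lagged recovery and the transient overshoot.
"""

import numpy as np

from recoverews import (FishingSchedule, SpeciesParams, build_size_grid,
                        run_simulation)

params = SpeciesParams()
grid = build_size_grid()
schedule = FishingSchedule(plateau_F=0.6, decline_rate=0.10)

series = run_simulation(params, schedule, grid, seed=1, burn_in="fast")

print(f"{'year':>6} {'F':>5} {'biomass (kt)':>13} {'mean size (g)':>14} "
      f"{'SD size (g)':>12}")
for year in (2010, 2039, 2045, 2050, 2060, 2070, 2090, 2150):
    i = int(year - series.years[0])
    print(f"{year:>6} {schedule.F(year):>5.2f} "
          f"{series.biomass[i] / 1e9:>13.2f} {series.mean_size[i]:>14.0f} "
          f"{series.sd_size[i]:>12.0f}")

post = series.years > 2039
peak = int(series.years[post][np.argmax(series.biomass[post])])
print(f"\nBiomass bottoms out during the plateau, recovers only after the "
      f"release\nand overshoots its new equilibrium around {peak} before "
      f"settling - the mean\nand SD of body size rise ahead of the biomass "
      f"recovery.")
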