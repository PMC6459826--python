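"""Compute the four stability indicators and a composite warning signal.

From one released replicate: CV and AR(1) of biomass (expanding window from
2010), the yearly mean/SD body size, each running-normalised (z-scored
against its own history), and their sum for the headline composite
AR(1) + SD size.  Values above 2 are warning signals of recovery.
"""

from recoverews import (DetectionConfig, FishingSchedule, SpeciesParams,
                        build_size_grid, consecutive_filter, detect_signals,
                        run_simulation)
from recoverews.ewsr import compute_composites

params = SpeciesParams()
schedule = FishingSchedule(plateau_F=0.6, decline_rate=0.02)
series = run_simulation(params, schedule, build_size_grid(), seed=1,
                        burn_in="fast")

composites = compute_composites(series, analysis_start_year=2010)
metric = composites["AR(1) + SD size"]

cfg = DetectionConfig(threshold_sigma=2.0, consecutive_k=2,
                      training_window=(2010, 2039),
                      assessment_window=(2040, 2090))
signals = detect_signals(metric, cfg)
detections = consecutive_filter(signals, k=2)

print("AR(1) + SD size composite (sum of two running z-scores):")
for year in (2030, 2040, 2050, 2060, 2070, 2080):
    v = metric.values[metric.years == year][0]
    print(f"  {year}: {v:6.2f}")
print(f"\nsingle-rule signal years (composite > 2 sigma, 2040-2090): "
      f"{signals.min()}..{signals.max()} ({signals.size} years)")
print(f"first 2-consecutive-year detection: {detections.min()}")
print("\nThe composite sits near zero through the collapse plateau "
      "(training years are\nnever counted as signals) and climbs past the "
      "2-sigma line as the release\ntakes effect - years before the actual "
      "biomass recovery.")
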