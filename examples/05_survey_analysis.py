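"""Warning signals of recovery in ICES-style survey data.

Builds the two synthetic survey fixtures (a recovering stock with
post-split rises in SSB and body size, and a stationary non-recovering
one), runs the pipeline with the half-split training protocol, and
reports which of the 15 composite metrics show 2-consecutive-year signals.

Real data would arrive as the same two tables: ssb.csv (year, ssb) and
sizes.csv (year, size - one row per measured fish).
"""

from recoverews import make_survey_fixture, run_survey_ewsr

for kind in ("recovering", "not_recovering"):
    series = make_survey_fixture(kind)
    report = run_survey_ewsr(series, train_fraction=0.5)
    firing = report[report.has_consecutive]
    print(f"{kind}: {len(firing)} of 15 metrics show >= 2 consecutive "
          f"signals at 2 sigma")
    if len(firing):
        row = firing[firing.metric == "AR(1) + SD size"]
        if len(row):
            years = row.iloc[0].consecutive_years
            print(f"  AR(1) + SD size detections: {years}")

print("\nConsecutive 2-sigma signals appear only in the recovering stock "
      "- the same\ncontrast the method shows between recovering and "
      "non-recovering cod stocks.")
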