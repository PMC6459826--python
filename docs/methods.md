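# Methods

## The surrogate population model

The simulator is deliberately a *surrogate*: a single cod-like species
whose purpose is to reproduce the statistical structure of
collapse-and-release dynamics in a multispecies size-spectrum community —
depressed biomass under sustained fishing, lagged non-linear recovery when
pressure is released, transient overcompensation at fast release rates,
and rising mean/SD body size ahead of biomass recovery — while staying
desk-scale and dependency-free. It is not a parameterisation of any real
stock, and its absolute scales (biomass in grams, egg numbers) are
internal conveniences.

Abundance density N(w, t) (individuals per gram of body mass) follows a
transport equation on a 100-class logarithmic grid spanning egg mass
(0.001 g) to the asymptotic mass (40 000 g):

    ∂N/∂t + ∂(g(w) N)/∂w = −(μ(w) + F(t)·1[w > w_sel] + μ_c(w, t)) N

* **Growth** g(w) = g0·w·(1 − w/w_inf), near-exponential in mass with a
  taper at the asymptotic mass; g0 = 1.2 /yr gives ~8 kg in a little over
  a decade from the egg. The exponent b = 1 is deliberate: with explicit
  upwind advection at the 0.1-yr sub-step, the CFL stability bound
  g·dt ≤ Δw is uniform across a log grid only when g ∝ w, which is what
  lets the grid span the full egg-to-asymptotic range.
* **Background mortality** μ(w) = μ0·w^c with μ0 = 1.7 /yr (at 1 g) and
  c = −0.25, i.e. ~0.2 /yr for large adults.
* **Fishing** is knife-edge above w_sel = 500 g; the schedule runs an
  unfished burn-in (1667–1966), a linear historic ramp from 0.25·F_plateau
  to F_plateau (1967–2009), a constant plateau (2010–2039, the collapse
  period) and a linear release from 2040 at 0–10 % of the plateau level
  per year. F_plateau defaults to 0.6 /yr.
* **Recruitment** enters the smallest class as a boundary flux,
  Beverton–Holt in spawner biomass S (fish ≥ 2 kg):
  R = R_max·S/(S + S_half) with R_max = 3×10^18 eggs/yr and
  S_half = 10^10 g. Egg-to-recruit survival happens inside the spectrum
  (hence the large capacity). Each calendar year the flux is multiplied
  by a mean-one log-normal deviate exp(σZ − σ²/2), σ = 0.05.
* **Cannibalism** adds mortality κ·S/S_ref (κ = 0.8 /yr, S_ref = 10^11 g)
  on individuals below 100 g. Pure Beverton–Holt dynamics cannot
  overshoot — the per-generation loop gain S_half/(S0+S_half) is below
  one, so release trajectories are monotone — whereas predation by
  rebuilding adults on juveniles is a delayed negative feedback that
  produces the transient overcompensation seen at fast release rates, and
  is the dominant density-dependent interaction in cod.

Numerics: first-order upwind differencing for growth (a configuration
error names the offending class if the CFL bound is violated), exact
exponential survival factors for all mortality terms per 0.1-yr sub-step,
recruitment noise drawn once per calendar year. Observables mimic a trawl
survey once per year: biomass, number-weighted mean and SD of body mass
over classes above the 10 g observation cutoff, with the (n−1)-denominator
analogue for the SD. The burn-in runs either in full from 1667 or in
"fast" mode from the cached noise-free unfished equilibrium at 1967; all
analysis windows lie decades later, where the two modes are statistically
indistinguishable.

## Calibration

F_plateau and the recruitment/cannibalism parameters were calibrated
jointly, once, against the behaviours the analysis depends on: plateau
biomass well below 30 % of the unfished level (default settles near 7 %);
recovery lagging the release (median recovery 2052 at 10 %/yr, 2080 at
2 %/yr); overshoot at fast release; and a control whose composite
indicators stay below their 2σ baseline. The last point is the subtle
one. Running z-scores are scale-free, so a control population fluctuating
around a *stationary* level false-alarms at a ~50–70 % rate over a
50-year window no matter how small the noise — the maximum of ~50
standardised values simply exceeds 2 too often. Low false-positive rates
require a *transient-dominated* control: the plateau F is set slightly
beyond the stock's replacement threshold, so the control keeps eroding
slowly (~1 %/yr) through the assessment window, its size-based indicators
sit below their running means, and the recruitment noise (σ = 0.05) is
small relative to these deterministic trends. This mirrors a community
model still settling under sustained pressure, and is a documented
property of the calibration rather than a claim about any real stock's
noise level.

## Indicators and detection

CV and AR(1) are computed on biomass over an expanding window from the
analysis start (2010); how wide the window should be is genuinely open,
and a trailing rolling window is available as an option
(`window_scheme="rolling"`). The AR(1) estimator is the OLS slope with
intercept of x_t on x_{t−1} — simple, exactly testable, standard in this
literature, not clamped to [−1, 1], and defined to return 0 on a constant
(zero-variance) window. Sample (n−1) SDs are used throughout. Mean/SD
size are the yearly survey observations themselves. Missing values (e.g.
AR(1) before three years of data) propagate: a composite is missing in
any year a member is missing rather than partially summed.

Normalisation follows the running z-score above, with the current value
included in both running statistics and ŵ defined from the second
defined year; a zero running SD yields ŵ = 0 with a degeneracy flag.
Composites sum the member ŵ series and are compared to the plain 2σ
threshold regardless of how many indicators are summed (the convention of
the composite-metric literature); an optional mode rescales the threshold
by √k under an independence assumption. Training-window exceedances are
discarded, but training data always feed the running statistics.

## Recovery times and evaluation

The recovery year is the breakpoint of the globally optimal single-break
piecewise-constant least-squares fit to biomass from the release year to
the series end (exhaustive search, minimum segment length 2, earliest
break on ties — all stated because generic descriptions of the method
leave them open). Fitting from 2040 keeps the long collapse plateau from
dominating the fit; the start year is configurable. A replicate with no
upward shift (second-segment mean not exceeding the first by 10 %
relative) is classed non-recovered; this margin rule only marks
replicates for exclusion — treatment labels, not the rule, decide TP/FP
accounting, with controls assessed over the fixed 2040–2090 window.

Lead time is recovery year minus the *first* qualifying detection. SEs
are sample SDs over replicates divided by √n. ROC curves sweep the
threshold over 0.01–6σ (the 2σ operating point is always on the grid)
and pool the five release rates into one TPR (per-rate curves are an
option). The training-length sweep re-runs the entire pipeline with the
analysis start moved so exactly L ∈ {2..30} training years precede the
release.

## Survey pipeline

Real inputs are two pre-tidied tables — annual SSB and individual body
sizes — since the analysis consumes only per-year moments and SSB;
survey-exchange-format parsing is out of scope. SSB plays the biomass
role. Sizes are analysed as-is (no length–weight conversion; the trait
column is whatever the survey measured). Training is the first
⌈fraction·n⌉ analysis years (default half). The synthetic fixtures
emulate a recovering stock (post-split upward shifts in SSB, mean size,
SD size) and a stationary non-recovering one with AR(1)-smoothed
interannual noise, 200 measured fish per year; the shipped seed is chosen
so the non-recovering fixture shows no 2σ signals at all. What the
fixtures do *not* emulate: gear changes, spatial coverage shifts,
age-truncation effects and the heavy-tailed noise of real surveys —
passing tests show the pipeline's logic, not field performance.

## Problem sizes

The test suite simulates 50 replicates of each of the six treatments
(fast burn-in) for the ensemble-level checks, and the acceptance script
100 replicates of control + 2 %/yr — sizes at which the reported
proportions are stable to a few percentage points and a full run stays
comfortably within a coffee break. The `full` config profile (300
replicates, full 1667 burn-in, 1800 runs) reproduces the original design
scale in under an hour.

## Known limitations

* Single species: no multispecies predation kernels or background
  resource dynamics; the cannibalism term is the only interaction.
* The historic 1967–2010 fishing history is a linear ramp, not the
  recorded series; only the post-2010 window feeds the analysis.
* The treatment list uses 0.025 /yr for the "40-year" release (2.25 %/yr
  would take ~44 years to reach zero; the discrepancy between the stated
  rate and duration is recorded, not resolved).
* Detection performance at the default calibration is sharper than the
  original multispecies experiment (TP ≈ 100 %, FP ≈ 0–3 % vs. 86 %/13 %):
  the surrogate's control is cleanly transient-dominated where a
  12-species community adds structured variability. The directional
  claims — high TP, low FP, the consecutive rule strictly more cautious,
  ROC monotonicity, recovery-time ordering — are the robust content.
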