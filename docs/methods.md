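# Methods

## Model structure

Two strategies are compared for surgical patients: a single prophylactic
dose of ramosetron 0.3 mg IV versus no antiemetic (saline, costed at 0).
A decision tree with three health states — no PONV, mild PONV,
moderate-to-severe PONV — is evaluated over a 5-day postoperative horizon.
Costs and outcomes are not discounted (the horizon is days, not years).
Anesthesia and routine postoperative care are assumed identical across
arms and excluded.

Each arm's time to PONV onset follows a parametric
accelerated-failure-time (AFT) law in the survreg convention: log event
time = μ + σ·ε, σ = exp(log-scale). For the Weibull family
S(t) = exp(−exp((ln t − μ)/σ)). The published per-arm Weibull parameters
are μ = −2.0997, ln σ = 0.8475 (ramosetron) and μ = −2.7831, ln σ = 0.7985
(no antiemetic); the packaged fixture reads their time unit as days. Day d
of the model covers (d−1, d]; its onset probability is S(d−1) − S(d), with
a fractional terminal day weighted proportionally. Day 1 onsets use the
acute (0–24 h) severity split, all later days the delayed (24–48 h) split,
extended over the extrapolated tail.

A patient experiences at most one PONV onset (single-episode convention);
the day-of-onset probability drives both the utility decrement and the
episode-driven costs. Expected treated episodes per patient =
cumulative onset probability × episodes-per-PONV-patient (default 1; the
calibration solves it per arm, landing at ≈1.02 for the no-antiemetic arm
and ≈0.82 for ramosetron).

## QALYs

QALY = Σ_d w_d·[(1−P_d)·u_no + P_d·(mild_d·u_mild + sev_d·u_sev)] / 365.25,
with utilities u_no = 0.90, u_mild = 0.70, u_sev = 0.24 (SEs 0.09, 0.07,
0.02) and w_d the fraction of day d inside the horizon. The source
literature also quotes 0.2 for the worst state; 0.24 is the tabulated
input and is used. Summing utilities over all 5 days is the default: a
4-day sum caps QALYs at 0.00986, below the published ramosetron value of
0.0121, while the 5-day cap is 0.01232; the 4-day reading remains
available via `qaly_days=4`.

## Costs and perspectives

All monetary values are USD, converted from KRW at the fixed study rate
1 KRW = 0.00073 USD, rounded half-up to cents at reporting only (this
reproduces every published KRW/USD pair to the cent; internal arithmetic
is unrounded). Components:

| component | formula | perspective |
|---|---|---|
| prophylaxis | arm drug cost (0 for comparator) | payer |
| rescue medication | Σ_d p_d·epp·(mild_d·c_mild + sev_d·c_sev) | payer |
| staff time | E[N]·(2/60·$53.92 + 14/60·$15.72) | payer |
| hospitalization | p_stay·1.67 d·$188.29/d | payer |
| outpatient visit | p_visit·0.67·$23.22 | payer |
| transportation | p_visit·0.67·$8.94 | societal |
| patient time | p_visit·0.67·$32.56 | societal |
| productivity loss | p_stay·1.67 d·$104.72/d | societal |

The default rescue regimen maps mild PONV to metoclopramide ($0.27) and
moderate-to-severe PONV to dexamethasone + palonosetron ($11.03); it is a
declared modelling default (the source does not print one) and is
configurable. Patient time uses the published per-visit wage loss rather
than an hourly computation. Adverse-drug-event treatment costs are an
optional per-episode add-on defaulting to 0 (their incidence was
panel-elicited and never printed). Service-use proportions (additional
stay 0.0833 / 0.1333; outpatient visit 0.02) apply unconditionally at arm
level, matching how they were elicited; `gate_hospitalization_on_severe`
and `gate_visits_on_event` optionally scale them by the PONV probability
instead (under those gates, zero PONV implies zero cost for the comparator
arm).

## Calibration to the published base case

The published inputs and outputs are mutually inconsistent: the Weibull
laws read in days imply 91% (ramosetron) and 97% (no antiemetic) PONV by
day 1 — incompatible with the published QALYs of 0.0121 / 0.0114 — and the
published hospitalization ($0.07 / $3.92) and rescue components are ≈11×
and ≈3× away from any product of the published unit inputs (hours as the
time unit is worse, implying ~100% day-1 incidence). No hidden rescaling
is guessed. Instead, calibrated mode anchors each arm to the published
outputs, which are shipped as an input fixture:

1. **Event multiplier m**: the QALY deficit is linear in a multiplier on
   the daily onset probabilities, so m solves the published arm QALY in
   closed form; it is clipped to [0, 1] so that calibrated onset
   probabilities remain valid at any horizon the sensitivity analyses may
   draw. Ramosetron: m ≈ 0.266 (QALY 0.0121 exactly). No antiemetic: the
   published 0.0114 is unreachable even at m = 1 (it would need >100%
   onset), so m clips to 1, giving 0.011429 — equal to the published value
   at its printed precision.
2. **Episodes per patient**: solved from the published staff-time
   component (staff cost per episode is fully determined by published
   wages and minutes).
3. **Component anchors**: each component is multiplied by
   published/structural evaluated at the base case, so the calibrated base
   case reproduces the published component table exactly while parameter
   draws still propagate multiplicatively through the structural formulas.
   Anchors are computed at run time from the fixture, never stored.

The calibrated ramosetron totals ($16.88 payer, $16.89 societal) equal the
published totals; the no-antiemetic totals ($17.34 / $18.73) exceed the
published ones ($17.33 / $18.72) by one cent because the published
component column itself sums to one cent more than the published total
(the source rounded components and totals independently). The package
reports its own computed ICER (payer ≈ −$686/QALY, societal ≈
−$2,742/QALY, both dominant); the source prints the payer ICER three
mutually inconsistent ways (−$1,080.88, −$636, and ≈−$643 from its own
rounded components).

## Sensitivity analyses

**One-way / tornado.** Each bounded cost, time, count or utility input is
set to its low then high bound (ranges are the published 95% CIs, or ±10%
where no CI was published; utilities use point ± 1.96·SE with the no-PONV
utility capped at 1). The ICER is recorded at both bounds and parameters
ranked by |ICER_high − ICER_low|. The panel-elicited proportion parameters
(severity splits, service use) are excluded from the default tornado —
the published one-way analysis varied the main input table only — but can
be passed explicitly. Calibration stays frozen at base case so the
variation propagates structurally. With the default scope the widest payer
bar is the ramosetron cost (one-way ICER range ≈ −$1,900 to +$2,400/QALY,
the same sign pattern as the published −$3,050 to +$800), matching the
published payer ranking; the published societal top bar ("duration of
analysis") is not reproduced — in this implementation the horizon moves
costs and QALYs only through the small extrapolated tail, and whatever
duration-cost channel produced the published bar is not derivable from the
printed inputs.

**PSA.** Per iteration every non-fixed parameter is redrawn once, shared
across arms: gamma for costs, beta for probabilities and utilities, normal
for times and counts, each moment-matched to (mean, SE); SE defaults to
(high − low)/3.92 when only a range is stated. The tabulated distribution
assignment is followed where it conflicts with the narrative assignment
(which puts utilities under gamma); beta keeps utility draws in [0, 1],
and the parameter validator enforces beta/fixed for probabilities and
utilities. Draws outside the natural support (negative costs/times, u
outside [0,1] under normal) are redrawn, not clamped, to preserve the
matched moments (cap 1000 redraws, then error). Default 1000 iterations,
single `numpy` Generator seeded explicitly, bit-reproducible. Summaries
use empirical percentile intervals (numpy's linear interpolation); per-draw
ICER percentiles are reported with the caveat that ratio percentiles mix
quadrants. The CEAC reports the fraction of draws with positive net
monetary benefit over a λ grid of −$20,000…$20,000/QALY in $500 steps.

A reproducibility note: with the stated utility SEs propagated, the
moment-matched beta for the no-PONV utility is Beta(9.1, 1.01), whose
heavy left tail (7% of draws below 0.75) occasionally collapses the QALY
gain. The resulting probability of cost-effectiveness at $5,000/QALY is
≈97.5% (payer) and ≈99.4% (societal) averaged over five seeds, versus the
published ">99% under both perspectives". The published arm-QALY 95% CI
(0.0121–0.0122, width 0.0001) could not have arisen from sampling the
stated utility SEs at all — the SE of 0.09 alone implies an arm-QALY SD of
≈0.0012 — so the published PSA evidently did not propagate the utility
uncertainty it declares; this package does, and documents the difference
rather than shrinking the inputs.

## Synthetic data

No patient-level times are published (the source pooled 271 patients from
three trials). `simulate_event_times` draws from any of the four AFT
families by inverse-CDF sampling (Weibull: T = exp(μ + σ·ln(−ln U)), so
S(T) = U) with administrative censoring at the study horizon;
`proportions_to_pseudo_ipd` expands 24 h/48 h cumulative proportions into
pseudo individual-patient data with events at interval midpoints (right
endpoints optionally) and survivors censored at the horizon. These
generators emulate the statistical structure the fitting stage assumes —
i.i.d. AFT event times with administrative censoring — and none of the
things real pooled trial data would add (between-trial heterogeneity,
covariates, informative censoring); passing recovery tests therefore
demonstrates correctness of the fitting code, not adequacy of the AFT
model for real PONV data.

## Numerical choices

- AFT maximum likelihood is delegated to lifelines' univariate fitters
  (deterministic given data); parameters are converted to location/scale
  form. Tests verify the reported log-likelihood against an independent
  closed-form + grid-search oracle to 1e−3.
- Model selection: minimal AIC, ties by minimal BIC, then fewer
  parameters — a total order.
- Beta/gamma moment matching: gamma shape = m²/s², scale = s²/m; beta
  ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν; an SE too large for the beta
  support is an error, not silently truncated.
- Currency rounding half-up (decimal, not banker's) to cents, at
  reporting only. Reports print USD to 2 decimals, QALYs and
  probabilities to 4.
- Severity splits must sum to 1 within 1e−9; interval probabilities over
  a partition reconcile within 1e−12.
- Percentile CIs refuse n < 40 rather than widening quantiles.

Problem sizes used in the test suite (parameter recovery at n = 2000 and
20 000, distributional checks at n = 10⁴–10⁵ draws, PSA convergence at
5000 iterations, acceptance PSA at 5 × 1000 iterations) were chosen so
each check's Monte-Carlo error is several times smaller than its assertion
tolerance.

## Known limitations

- The calibrated mode is an anchoring, not an estimation: it reproduces
  the published base case by construction and therefore cannot validate
  it; the uncalibrated (structural) mode is the self-consistent model.
- The time unit of the published AFT laws is undocumented at source; days
  is a configuration default, and under it the raw laws overpredict PONV
  severely (hence the calibration).
- Parameter correlations are not modelled (none were published).
- No EVPI/EVPPI, no microsimulation, no covariate-adjusted AFT fitting.
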