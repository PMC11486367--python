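# ponv-cea

A decision-analytic cost-effectiveness model of **prophylactic ramosetron
versus no antiemetic therapy** for postoperative nausea and vomiting (PONV),
from the South-Korean healthcare-payer and societal perspectives.

PONV affects roughly 40% of surgical patients in Korea; a single
intravenous dose of ramosetron (0.3 mg, $13.94) before emergence can
prevent much of it. The package answers the health-economic question: does
paying for universal prophylaxis cost less, per quality-adjusted life year
(QALY) gained, than treating PONV when it occurs?

## The model

A two-arm decision tree is evaluated over a 5-day postoperative horizon
(no discounting). For each arm:

- **Time to PONV onset** follows a Weibull accelerated-failure-time law,
  `S(t) = exp(−exp((ln t − μ)/σ))`, with published per-arm location μ and
  log-scale ln σ; the day-d onset probability is `S(d−1) − S(d)`,
  extrapolated over the full horizon. Fitting (exponential, Weibull,
  log-logistic, log-normal; AIC/BIC selection) is supported for
  pseudo-trial data generated by the `synthetic` module.
- **Severity**: onsets split into mild vs moderate-to-severe states using
  panel-elicited proportions (separate 0–24 h and 24–48 h splits).
- **QALYs**: `Σ_d [(1−P_d)·u_no + P_d·(mild_d·u_mild + sev_d·u_sev)] / 365.25`
  with utilities 0.90 / 0.70 / 0.24.
- **Costs** (USD, KRW converted at 0.00073): prophylaxis, rescue
  medication, physician/nurse time, additional hospitalization and
  outpatient visits (payer perspective); plus transportation, patient time
  and productivity loss (societal perspective).
- **Calibrated mode** anchors each arm to the published base-case outputs
  (see `docs/methods.md`), since the published survival parameters and
  cost components are mutually inconsistent as printed.

Incremental analysis reports ΔC, ΔQ, the ICER `ΔC/ΔQ` and dominance;
one-way analyses feed a tornado ranking; probabilistic sensitivity
analysis (PSA) redraws all parameters (gamma costs, beta
probabilities/utilities, normal times/counts, moment-matched to the stated
mean/SE) and yields cost-effectiveness-plane draws, percentile intervals
and the cost-effectiveness acceptability curve (CEAC) via net monetary
benefit `NMB = λ·ΔQ − ΔC`.

## Worked example

```python
from ponv_cea import calibrated_base_case, incremental_analysis

outcomes, calibrations = calibrated_base_case()
ram, none = outcomes["ramosetron"], outcomes["no_antiemetic"]
print(f"ramosetron:    payer ${ram.total_payer:.2f}  societal ${ram.total_societal:.2f}  QALY {ram.qaly:.4f}")
print(f"no antiemetic: payer ${none.total_payer:.2f}  societal ${none.total_societal:.2f}  QALY {none.qaly:.4f}")
r = incremental_analysis(ram, none, "societal")
print(f"societal: dC = ${r.delta_cost:.2f}, dQ = {r.delta_qaly:.4f}, ICER = {r.icer:.0f} $/QALY ({r.dominance})")
```

prints

```
ramosetron:    payer $16.88  societal $16.89  QALY 0.0121
no antiemetic: payer $17.34  societal $18.73  QALY 0.0114
societal: dC = $-1.84, dQ = 0.0007, ICER = -2742 $/QALY (intervention_dominant)
```

Ramosetron is *dominant*: it costs less (the $13.94 dose is outweighed by
avoided rescue treatment, staff time and hospitalization) and yields more
QALYs, so the negative ICER is labelled rather than interpreted as a
ratio. The command-line interface writes the same results as report files:

```sh
ponv-cea base --out report                         # arm tables + incremental analysis
ponv-cea full --psa-iterations 1000 --seed 7 \
    --wtp-min -20000 --wtp-max 20000 --out report  # + tornado, PSA draws, CEAC
```

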