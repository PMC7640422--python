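# nipt-bia

Budget-impact microsimulation of **contingent cell-free-DNA screening (NIPT)**
in a universal public prenatal screening program for trisomy 21.

Quebec's program offers every pregnant woman a serum integrated prenatal
screen (SIPS: first-trimester PAPP-A plus second-trimester quad markers,
combined with maternal age; screen-positive at risk ≥ 1/300) followed by
confirmatory amniocentesis. Because most screen-positives are false
positives, the program performs many avoidable invasive procedures.
Inserting NIPT as a *contingent* second-tier test — offered only to
screen-positives, with amniocentesis reserved for NIPT-positives — trades a
new per-test cost against a large reduction in invasive testing. This
package asks the budget-holder's question: **what does the swap do to total
annual program expenditure**, from the public-payer perspective, over one
fiscal year, undiscounted?

It is written for health-economics and screening-program analysts who want a
tested, configurable re-implementation of this analysis: every parameter is
a published program quantity, every result is a Monte Carlo mean over
replicated virtual cohorts, and both strategy arms run on **common random
numbers** so the cost difference is estimated with far less noise than the
arm totals.

## Model

- **Virtual population.** One annual cohort of singleton pregnant women aged
  15–49: per-age pregnancy probabilities rescaled so the overall pregnancy
  rate is 5.95% of a ~1.88 M base population (≈ 111,752 pregnancies), and
  fetal trisomy-21 status drawn per pregnancy from a maternal-age risk curve
  spanning 0.10%–6.6%.
- **Weekly natural history.** From model entry (week 10) to term (week 40),
  two competing weekly hazards act on every ongoing pregnancy: spontaneous
  fetal loss (front-loaded; 13.5% cumulative for unaffected pregnancies,
  and for affected pregnancies anchored to conditional losses-to-term of
  36% / 30% / 25% / 21% at weeks 10/12/14/16) and voluntary induced
  abortion (90% first trimester / 10% second). Losses precede appointments
  within a week.
- **Pathways.** Current practice: screening offer (uptake 50%) → SIPS
  (detection 85%) → amniocentesis for positives (uptake 90%; perfect
  diagnostic; 0.11% procedure-loss and 1% fluid-leak risks) → genetic
  counselling and termination (uptake 90%) for confirmed cases. Contingent
  arm: identical through the SIPS result, then NIPT (uptake 90%, detection
  99.9%, false-positive 0.1%, 2% no-call with one retest) gates the
  amniocentesis. A choice variant routes a fraction of screen-positives
  straight to invasive testing.
- **Costs.** Eight billable items (CAD, fiscal 2015–16): SIPS 108.60, NIPT
  795 per attempt, amniocentesis 864.39, counselling 138.636, program
  administration 18.07 per participant, termination 1,632.48, procedure
  loss 2,919, leak hospitalization 2,971.
- **Calibration.** Four under-determined knobs (base-population scale,
  effective in-model termination total, risk-curve prevalence scale,
  effective SIPS false-positive rate) are pinned by monotone 1-D root
  finding to four published aggregates: 111,752 pregnancies, 41,904
  screening participants, 1,773 current-arm amniocenteses, 114 confirmed
  diagnoses.

## Worked example

```python
from nipt_bia import default_config, calibrate, run_experiment, build_bia_report

cfg, record = calibrate(default_config())
report = build_bia_report(run_experiment(cfg, n_replicates=500))
print(f"current practice total:  {report.overall['current']:,.0f} CAD")
print(f"contingent NIPT total:   {report.overall['contingent']:,.0f} CAD")
print(f"difference (con - cur):  {report.mean_difference:,.0f} CAD")
print(f"95% CI:                  {report.ci[0]:,.0f} to {report.ci[1]:,.0f} CAD")
```

prints

```
current practice total:  7,063,036 CAD
contingent NIPT total:   6,981,706 CAD
difference (con - cur):  -81,330 CAD
95% CI:                  -134,808 to -32,445 CAD
```

i.e. the contingent strategy is roughly cost-neutral, saving ≈ 81 k CAD
(≈ 1.2% of the ~7.06 M CAD current-practice budget) per year: the
~1.43 M CAD added by ~1,800 NIPT attempts is offset by the ~1.44 M CAD
removed with ~1,666 avoided amniocenteses, plus small savings from fewer
procedure-related losses, leak hospitalizations and terminations. The CI is
the percentile interval of the *per-replicate* difference (between-cohort
variability), not the much tighter standard error of the mean.
`report.to_dataframe()` gives the full itemized table; `ScenarioSpec` +
`run_univariate_sensitivity` rerun any dotted config parameter on shared
seeds, and `run_choice_scenario` models screen-positives choosing between
NIPT and direct invasive testing.

The same operations are exposed on the command line:

```bash
nipt-bia simulate --reps 200 --seed 1 --out out/
nipt-bia sensitivity --reps 200 --out sensitivity.csv
nipt-bia choice --p-direct 0.20 --p-nipt 0.725
```

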