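# Methods

## Model structure

The simulator is a discrete-time (weekly-cycle) microsimulation of one
annual cohort of singleton pregnancies, followed from gestational week 10 to
delivery at week 40. Each woman carries a maternal age, a fetal trisomy-21
status fixed at entry, a pregnancy state and a screening-pathway state. Two
strategies are compared on the same cohort: current practice (serum
integrated screening, SIPS, with amniocentesis for screen-positives) and
contingent NIPT (SIPS, then NIPT for screen-positives, then amniocentesis
for NIPT-positives). The outcome is the itemized direct cost to the public
payer over one fiscal year, undiscounted, and the between-arm difference.

Two implementations share the same semantics: a vectorized engine
(`engine.simulate_replicate`) that resolves the whole cohort with boolean
mask algebra — a ~112k-agent arm-replicate runs in tens of milliseconds —
and an agent-based reference (`engine.simulate_replicate_agents`) built on
the per-woman operations in `pathways`/`natural_history`, which also
produces full per-woman event logs. The two are cross-validated
statistically in the test suite; both are checked against a brute-force
weekly enumeration of the competing-risk process.

## Natural history

Within each week, events are evaluated in a fixed order: spontaneous fetal
loss, then voluntary induced abortion, then any scheduled screening
milestone. Scheduling losses ahead of appointments is the conservative
reading of program attrition (a woman lost in the week of her appointment
does not attend it).

**Spontaneous loss.** Unaffected pregnancies follow a geometrically
declining weekly hazard `h0 * r^(w-10)` (default ratio r = 0.76, placing
roughly two thirds of losses before week 14, consistent with first-trimester
front-loading), with `h0` solved so the cumulative loss from entry to term
equals the configured total (default 13.5%). Affected pregnancies are
anchored to conditional losses-to-term — P(loss between week w and term |
ongoing at w) — of 36/30/25/21% at weeks 10/12/14/16; log-survival is
interpolated linearly between anchors and a constant weekly hazard from week
16 to 39 consumes the remaining 21%. Both constructions are exact (closed
form or Brent root-finding to 1e-14) and are asserted to 1e-6 in tests.

**Voluntary termination.** A uniform weekly hazard within each trimester
window (weeks 10–13 and 14–27) solves the window's share (90%/10%) of the
cumulative total exactly. The *in-model* total is a calibration knob
(published default 23%): part of the real-world terminations occur before
the model's entry week, so the effective total inside the modelled horizon
is smaller (calibrated ≈ 17.3%).

## Screening pathways and calendar

Milestones: screening offer with the first serum sample at week 12; quad
sample (and SIPS billing) at week 15; SIPS result at week 16. The
confirmatory amniocentesis is performed **in the same week the triggering
positive result is returned** — week 16 in the current arm (the program
schedules amniocentesis at 16 weeks alongside the result), week 17 after a
first-attempt NIPT positive, week 19 after a positive on the single retest
that follows a no-call. This same-week convention matters: each extra week
between the SIPS result and the contingent-arm amniocentesis removes ~1% of
affected pregnancies through their elevated loss hazard, and a
one-week-later calendar visibly understates the published contingent-arm
diagnosis and termination counts. Genetic counselling and the termination
decision follow one week after confirmation.

The biochemical risk computation behind the 1-in-300 cutoff is abstracted
into detection-rate / false-positive-rate Bernoulli draws by fetal status.
Amniocentesis is a perfect diagnostic; procedure-related loss (0.11%) and
amniotic-fluid-leak hospitalization (1%) are independent Bernoullis per
procedure, and a procedure loss pre-empts the diagnosis. Women who decline
any step revert to the natural course; an NIPT-negative result ends testing;
a second no-call ends testing (probability ≈ 4e-4). NIPT decliners do not
receive direct amniocentesis in the base contingent strategy — direct
invasive testing exists only in the explicit choice scenario, where
screen-positives split three ways (direct amniocentesis / NIPT / nothing).

## Costs

Eight billable items at fixed CAD 2015–16 unit prices; every NIPT attempt
(first draw and retest) is billed at full price; program administration is
billed once per screening participant; no discounting. Ledgers satisfy two
exact identities used as tests: total = sum of items, and item cost = count
x unit price. One-time NIPT implementation costs are out of scope.

## Replication, randomness and variance reduction

An experiment runs `n_replicates` paired replicates (default 1000, matching
the published protocol; desk-scale runs use 100–500). Each replicate draws a
fresh cohort from its own seed sub-stream; under the default
`shared_per_replicate` mode both arms consume the identical cohort and the
identical pre-drawn decision uniforms (common random numbers), so
strategy-invariant rows (SIPS tests, administration) cancel exactly and the
difference CI is driven only by pathway divergence. An
`independent_per_arm` mode is retained for sensitivity; its difference
variance is several-fold larger (asserted in tests). Seed discipline is a
stateless SeedSequence tree: (master seed, replicate index, stream index),
so any result is bit-reproducible from (config, master seed) and scenario
reruns sharing a master seed share all upstream draws. Sensitivity scenarios
deliberately use these shared seed blocks rather than independent reruns, so
scenario deltas isolate the parameter; under a pure price change the delta
is *exactly* price-slope x mean attempts.

The per-replicate confidence interval is the empirical 2.5/97.5 percentile
of the per-replicate overall difference; the published work does not state
its CI construction, and percentile-over-pairs was adopted.

## Calibration

Four quantities are under-determined by the published inputs and are pinned
to published aggregates, sequentially and in this order:

1. **Base-population scale** → mean pregnancies (111,752). The expected
   cohort size is exactly rate x base population, so this knob is solved in
   closed form rather than by simulation.
2. **Effective in-model termination total** → mean SIPS participants
   (41,904). Calibrated ≈ 0.173.
3. **Risk-curve prevalence scale** → mean confirmed-diagnosis counselling
   count, current arm (114). Calibrated ≈ 4.8 (the unscaled default curve is
   deliberately conservative at mid ages).
4. **Effective SIPS false-positive rate** → mean current-arm amniocenteses
   (1,773). Calibrated ≈ 4.45% — the published 3.3% input is arithmetically
   inconsistent with the published invasive-test count, which implies a
   screen-positive rate near the program-reported ~4.5%; the 3.3% remains
   the config default and the calibrated value is recorded in the
   calibration provenance record.

Knobs 2–4 use Brent root-finding on the simulated current-arm mean over a
fixed block of 48 replicates whose seeds are shared across every evaluation
(the simulated mean is then a monotone step function of the knob). 48 was
chosen so the block's Monte Carlo error is small against the 2% anchor
tolerance; each knob's target is empirically monotone over its bracket
(asserted on a coarse grid in tests).

## Synthetic population: what it does and does not emulate

The generator reproduces the aggregates that constrain the published
analysis — cohort size, overall pregnancy rate, participant counts, and the
maternal-age risk range — from a uniform base population with a Gaussian
relative-fertility shape (mode 29 y, sd 5.5 y) and an exponential-in-age
risk curve (doubling every ~2.5 y, clipped to 0.10%–6.6%). The true
maternal-age distribution and per-age fertility of the 2015 cohort are not
public in the source material, so age-conditional quantities (e.g. risk at
exactly age 40) are schematic; only the calibrated aggregates carry over to
real data. Passing tests therefore demonstrate fidelity to the published
totals and to the model's internal logic, not to person-level registry data.
Multiple pregnancies, maternal mortality, gestational-dating error,
mid-year conceptions, other aneuploidies and long-term costs of affected
births are out of scope.

## Numerical choices and degenerate inputs

- Ages are integer years; risks are clipped to [floor, cap] *after* the
  prevalence scale is applied, so a zero scale leaves every age at the
  floor (0.10%), never at zero.
- Ties between a spontaneous loss and a voluntary termination drawn in the
  same week resolve to the loss (it is evaluated first).
- A zero overall pregnancy rate, zero uptake, zero hazard totals and
  single-week termination windows are all exact special cases with tests.
- Per-age pregnancy draws use one binomial per age stratum, distributionally
  identical to per-woman Bernoullis; event weeks are inverse-CDF samples, so
  a shared uniform couples schedules monotonically across scenarios.
- Fractional counts in reports are replicate means (e.g. 0.12 procedure
  losses per year in the contingent arm).

## Known limitations

- The two published NIPT-uptake and two screening-participation sensitivity
  rows cannot be reproduced by any internally consistent pathway model: the
  published rows scale only first-order items (test volumes) while holding
  downstream counselling/termination rows — and, for participation, even the
  screening-test row itself — fixed. This package scales every downstream
  quantity with its driver, and its replication tests for those two
  scenarios document the discrepancy rather than imitate it.
- The calibration is a deterministic anchor-matching procedure, not a
  Bayesian posterior; parameter uncertainty beyond replicate noise is not
  propagated (no probabilistic sensitivity analysis).
- Costs are a single fiscal year; no discounting, no multi-year horizon, no
  societal perspective.
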