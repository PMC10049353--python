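# Methods

## Model structure

Both arms are rooted chance trees over the same cohort (HIV-positive
septic adults, TB prevalence 0.50). Terminal payoffs are (cost, QALY)
pairs under a cost-at-leaf convention: every leaf stores the total cost of
its path, so the expected value of an arm is a plain probability-weighted
average and agrees with exhaustive path enumeration to machine precision.
Probabilities are never renormalised silently; a chance node whose
branches do not sum to 1 within 1e-9 is reported as a violation, because a
bad sum in this model is a transcription error, not a rounding artifact.

The selective-treatment arm can be factorised either test-result-first
(marginal positivity, then PPV/NPV) or disease-first (prevalence, then
conditional test results). The two are rollback-equivalent — the law of
total probability PPV·P(+) + (1−NPV)·P(−) = π holds to 1e-12 and is
property-tested — so the choice is cosmetic; the test-first form matches
how clinicians traverse the tree and is the default.

The combined LAM+Xpert strategy uses the *tabulated* accuracy
(sensitivity 63.5%, specificity 99%), not an independence composition of
the two assays: either-positive independence would give
1 − 0.47·0.58 ≈ 0.727 sensitivity, well above the literature estimate,
because the assays' detection failures are correlated. An exploratory
`compose()` utility exists but is never used in the case study. The
combined diagnostic cost defaults to the sum of both assays
(4.19 + 17.42 = 21.61 USD), configurable, since no combined cost is
published.

## QALYs

Survivors accrue (1 − disability weight) × horizon; death accrues zero.
When the acute-sepsis decrement is on, the severe-sepsis weight (0.31) is
additionally applied over the first `acute_days` (default 7) of the
horizon, i.e. QALY = (1 − dw)·(h − 0.31·min(7/365, h)). Because this
multiplies all survivor payoffs by a common factor, it is observationally
equivalent to a small horizon shift and is kept mainly for transparency
of the accounting.

False positives (treated without TB) keep the no-TB mortality and the
HIV-on-ART utility with the treatment cost added: the inputs provide no
toxicity penalty, and inventing one would be a modelling claim the data
do not support.

## Structural axes and calibration

Three structural quantities are not derivable from the published inputs.
They are explicit `StructureConfig` fields, and `calibrate()` resolves
them by exhaustive search against the six reported values (incremental
effectiveness to its printed 2 d.p., ICERs unrounded), minimising the mean
relative error. The grid, declared once in `cea.CALIBRATION_GRID`:

* **mortality_mode** — `mortality_direct` (the directly measured 13.5%
  on-treatment mortality), `success_mediated` (80% success among the
  93.5% rifampin-susceptible; resistant patients fare worse), or
  `empiric_success_mediated` (arm-specific: the empiric regimen uses the
  success/resistance pathway — it was parameterised from the
  investigators' preliminary efficacy data — while confirmed-TB treatment
  under standard of care uses the direct mortality).
* **resistance_outcome** — resistant patients face untreated-TB mortality
  (first-line therapy fails) or stay on treatment at treated mortality;
  survivors remain in the TB/HIV state either way.
* **soc_delayed_empiric / delayed_uptake / delayed_survivor_state /
  count_delayed_treatment_cost** — whether missed-TB patients who survive
  the initial untreated period (day-7 survival of non-confirmed suspects,
  1 − 0.20) reach delayed empiric therapy; with what uptake (the
  `p_delayed_empiric` parameter, default 0.80, or full); whether its
  survivors end fully treated or still carry the TB/HIV disability for
  the horizon (treatment came late); and whether the delayed course is
  costed inside the analytic window (it starts after the day-3–5
  reassessment and can fall outside the trial's costed window).
* **sepsis_dw_applied** — acute decrement on or off.
* **horizon** — coarse grid 0.25–2.0 years in steps of 0.25, then a fine
  deterministic scan (5e-4, then 1e-4) around the best coarse point for
  the ten leading configurations. Ties resolve to the earliest
  configuration in declared order.

Defaults outside calibration are the conservative readings: direct
mortality, delayed empiric therapy on with parameterised uptake, treated
survivor state, delayed cost counted, sepsis decrement on.

### Why exact reproduction is impossible, and what calibration finds

In any tree where the two arms differ only on TB-status branches and
structure is shared across diagnostics, the QALY difference has the form
ΔE = ½[(A−C) − se·(B−C)], with A, B, C the treat-all, confirmed-treated
and missed-TB payoffs. The three reported (ΔE, ICER) pairs then
over-determine B−C: the Xpert/LAM pair implies B−C ≈ 0.432 while the
LAM/combined pair implies ≈ 0.400. No configuration can therefore hit all
six values exactly; the attainable optimum leaves ICER residuals of about
±1%. The calibrated configuration (arm-specific mortality; delayed
empiric with parameterised uptake; late-treatment survivors retaining the
TB/HIV weight; delayed course not costed; no sepsis decrement; horizon
0.8512 years) reproduces all three incremental-effectiveness values at
printed precision and the three ICERs to 0.85–1.21%. Consistently, the
incremental cost implied by the reported numbers equals
195·(1−P(+)) per strategy to four decimals, which is exactly the selective
arm costing treatment for test-positives only.

## Sensitivity analysis

One-way excursions use the published range when present and otherwise
±10% of base, multiplicative by default (an additive option exists),
clipped to [0,1] for probabilities and weights. The default tornado
varies exactly the parameters that carry published ranges — the input
table marks range-holders as the sensitivity-analysis set — and further
parameters can be included by name. Because every probability enters the
trees as a complementary (p, 1−p) pair, the sibling branch absorbs each
excursion; no other renormalisation is needed. Outcomes: QALY difference
(default, matching the published tornado) or ICER. Entries are sorted by
descending spread with name tie-breaks for reproducibility.

Under the calibrated axes with the success/resistance factorisation, the
rifampin-susceptible treatment-success rate has the largest spread,
day-7 survival of non-confirmed suspects ranks above the resistance
proportion, and with full delayed uptake plus resistant patients kept on
treatment, untreated-TB mortality lies on no path and has spread exactly
zero — the structural reading under which it "does not contribute".

## Synthetic data

The package needs no external data. Two generators make every stage
testable:

* `perturb_parameters` draws independent uniform values inside each
  published range (falling back to ±10% where no range exists, with a
  logged notice), clipped to [0,1]; draws are deterministic per seed and
  independent across parameters — no correlation structure is published,
  so none is invented.
* `simulate_cohort` walks seeded virtual patients through any validated
  tree, sampling every chance node (vectorised per node in preorder from
  a single named RNG stream, so results are independent of any execution
  plan and byte-reproducible given (tree, n, seed)).

What passing these tests shows is internal consistency — the analytic
rollback, the path enumerator and the simulator agree across the
parameter space — not external validity: the generators emulate the
model's own stochastic structure, not patient-level heterogeneity,
correlated diagnostic errors, time-varying mortality, or anything else
real cohorts would add.

## Numerical choices

* Rollback and enumeration are plain double-precision sums; agreement is
  asserted at 1e-12 relative. Monetary inputs pass through `Decimal` at
  parse time so printed cents are exact (4.19 + 17.42 = 21.61); internal
  arithmetic is float, rounded to cents only at display/serialisation.
* Microsim-vs-rollback comparisons use 4 standard errors plus an absolute
  floor of 1e-9·max(1, |ref|): an arm whose leaves all carry the same cost
  has sample SE ≈ 1e-17 of pure float noise, and a relative floor is the
  correct guard, not a loosened z-bound.
* Problem sizes: the oracle suite runs 50 perturbed parameter sets × 6
  arms × 100,000 patients (about 15 s); calibration evaluates ~10,850
  model configurations in a few seconds.
* Probability-sum tolerance is 1e-9; categorical sampling guards the
  u ≈ 1 searchsorted edge case explicitly.

## Known limitations

* No Markov/state-transition extension, discounting, half-cycle
  correction, probabilistic sensitivity analysis, CEACs or EVPI: the
  artifact models the short trial horizon only.
* The calibration identifies *a* best-fitting structural reading, not
  *the* one used originally; the per-target residuals quantify exactly
  how far each reading is from the reported numbers, and the reported
  ICERs are themselves mutually inconsistent at printed precision (see
  above), so residuals of ~1% are the floor, not a fit failure.
* CD4 strata, ART transitions, second-line therapy for resistant TB and
  newer LAM assays are out of scope; specimen obtainability is folded
  into assay sensitivity, as in the inputs.
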