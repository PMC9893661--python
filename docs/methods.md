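# Methods

## Model structure

The model is a cohort-level state-transition (Markov) simulation over three
coarse disability states — mRS0–2 (functionally independent), mRS3–5
(disabled) and mRS6 (death, absorbing) — with a one-month cycle. The trace
has 58 time points (months 3, 4, …, 60 since onset) and 57 transitions: the
initial distribution sits at month 3, when patients leave convalescent care,
and the first transition lands on month 4. No half-cycle correction is
applied. Recovery (mRS3–5 → mRS0–2) is permitted only for transitions whose
destination month is at most `recovery_window_months` (default 12, i.e. the
first post-onset year; the alternative reading "first 12 cycles" is
available by setting the window to 15). A worsening transition
(mRS0–2 → mRS3–5) exists as a calibratable parameter but is frozen at 0 by
default, since the model diagram guarantees only recovery and death arrows.

The two arms share the entire transition schedule and differ only in

* the initial distribution — control 37.6 / 58.5 / 3.9 (%); intervention
  mRS0–2 = 37.6% × RR with the death share held equal and mRS3–5 taking the
  remainder (1 − 0.4926 − 0.039 = 0.4684; the source prints both 47.0% and
  46.7% for this quantity, and we keep the constructed value); and
* the acute-stage rehabilitation cost.

Coarse occupancy is split into fine grades with fixed proportions
(mRS0:1:2 = 30.5:29.8:39.6, mRS3:4:5 = 37.5:36.9:25.6), renormalized to sum
exactly to 1 (the first triple prints as 99.9%), and held constant over the
horizon.

## Mortality anchoring and calibration

Monthly death probabilities are the age-matched general-population monthly
mortality — `1 − (1 − q_annual)^(1/12)`, which inverts exactly under
12-cycle compounding — multiplied by a state-specific mortality risk ratio.
Attained age advances annually: the transition landing on month m uses the
life-table row for age 75 + ⌊(m − 1)/12⌋.

The free parameters (RR_mRS02, RR_mRS35, monthly recovery probability) are
fitted by unweighted least squares against landmark targets: cohort survival
*conditional on being alive at month 3*, plus (optionally) the share of
survivors who are independent. Two state-specific mortality ratios are used
rather than one shared ratio because a single ratio cannot move the
independence-among-survivors trajectory; a config switch
(`calibration.tie_mortality_ratios`) ties them when a single-ratio reading is
wanted. The optimizer is a deterministic coarse grid (10 points per
dimension over RR ∈ [1, 20], p ∈ [0, 0.2]) followed by bounded Nelder–Mead
refinement from the eight best grid points — the multiple starts guard
against a near-symmetric local minimum in which the two mortality ratios
almost swap roles. The objective is evaluated through a fast two-state
recursion; the full schedule/trace engine recomputes the residuals at the
optimum, so the two code paths check each other. Parameter recovery on
synthetic targets is exact to ~1e-9 in the tests.

Beyond month 60 (the 10-year scenario) the schedule is extended reusing the
fifth-year non-mortality parameters while death probabilities keep tracking
attained-age life-table mortality times the same ratios.

## Costing and outcomes

Acute rehabilitation: day 1 is the onset day; the chargeable windows are
onset-days 1–30 (base fee $18.6/unit + $2.41/unit surcharge) and onset-days
1–14 (further $3.62/unit), at 4.3 units/day. Both surcharges attach to every
delivered unit in their window with no cap. The everyday arm's cost is
onset-invariant ($2928.21); the Mon–Fri arm is averaged over the seven
equiprobable onset weekdays ($2091.58 — a 14-day window always contains
exactly 10 weekdays, a 16-day window 80/7 on average). The conservative
Mon–Fri reading of "5 days a week" is used; other patterns are expressible.
Convalescent-stage medical costs (months 2–3) are excluded by assumption, so
acute rehabilitation fees are the only medical cost difference.

Long-term care: each fine grade maps to a utilization rate and a care-needs
level mix (mRS4 → Care 2:3 = 60.8:39.2, mRS5 → Care 4:5 = 61.0:39.0) whose
monthly costs are combined as expected values — the model is cohort-level,
so stochastic per-patient level assignment has no meaning here. Grades mRS0
and mRS6 incur no cost. LTC costs and QALYs accrue from month 4 (the Markov
window); months 1–3 contribute neither, since their handling is not
specified in the source — `model.accrue_from_month` exposes the alternative.
This choice shifts absolute per-arm QALYs but barely touches the deltas.
Cashflows in month m are discounted by (1 + r)^(−(m−1)/12) with r = 2%/year;
the acute cost (month 1) is undiscounted. QALYs weight occupancy by
grade utilities (0.89 / 0.797 / 0.65 / 0.588 / 0.363 / 0.092 / 0), each
month contributing 1/12 of a year.

Perspectives: healthcare ICER = Δmedical/ΔQALY; combined ICER =
Δ(medical + LTC)/ΔQALY. Δcost < 0 with ΔQALY > 0 is reported as *Dominant*,
the reverse as *Dominated*, ΔQALY = 0 as *Undefined*; ratios are reported in
whole USD/QALY with unrounded internals. Results are per patient and
invariant to any nominal cohort size.

## Sensitivity analysis

One-way DSA (efficacy initial distribution 45.0%/53.8%; fine splits to
all-best/all-worst grade; LTC utilization ±10% capped at 1; rehabilitation
and LTC fees −50%/+100%; units/day 1/9) re-runs the analysis with one
parameter moved, sharing the calibration (no DSA parameter enters it), and
orders rows by healthcare-ICER span. Fees and units/day scale Δmedical — and
hence the healthcare ICER — exactly linearly; the tests assert those
identities to 1e-9. The published upper ICER at 9 units/day (≈×1.36 of base)
is inconsistent with uncapped linearity (×9/4.3 ≈ 2.09); no undocumented cap
is implemented and that printed value is not used as a check.

PSA (1000 iterations, seeded, bit-reproducible): risk ratio ~
Normal(1.31, 0.05) and units/day ~ Normal(4.3, 1.0), both read as
mean/standard-deviation (a variance of 0.05 would be implausibly wide
against the published CI); utilities and care-level costs ~ Gamma(shape,
rate). All draws are independent, per iteration (a cohort model has no
per-patient state). Truncation policy, with counts logged in the summary:
risk-ratio draws clipped so the derived initial distribution stays on the
simplex, units/day re-drawn while non-positive, utility draws capped at 1.
The utility gamma pairs reproduce their point utilities to within 0.01
(e.g. 61.0/68.5 = 0.8905); the care-cost gamma pairs do *not* reproduce the
printed monthly costs under either (shape, rate) or (shape, scale) — they
are implemented as (shape, rate) with per-level config overrides, which
shifts PSA cost-draw means below the deterministic values but leaves both
acceptability summaries at 100% with a wide margin. The acceptability
criterion counts dominant iterations as below the threshold.

Scenarios: discount 0% and 4%, and a 120-month horizon via schedule
extension.

## Synthetic inputs and what the tests show

The life table defaults to a synthetic two-parameter Gompertz form,
q(age) = q75·exp(slope·(age−75)) with q75 = 0.018 and slope = 0.115/year —
a realistic approximation to elderly Japanese all-population mortality —
and any `age,qx` CSV replaces it. Calibration targets default to a packaged
**synthetic stand-in** CSV whose five survival landmarks (0.91/0.82/0.74/
0.67/0.60 at months 12–60, conditional on month-3 survival) and independence
shares (0.42/0.46/0.50 at months 12/36/60) were fixed once from general
knowledge of population-based elderly stroke cohorts. Synthetic targets for
testing are generated by running the forward model at a known ground truth
and reading off the landmarks, which makes parameter recovery a genuine
round-trip oracle.

Consequently the tests establish: the fee arithmetic and epidemiological
derivations to the printed dollar/ratio values; every structural invariant
(conservation, death monotonicity, discounting monotonicity, linearity,
dominance across the DSA grid, seeded reproducibility); and that the
calibration machinery identifies its parameters. They do **not** establish
the published base-case magnitudes (ICER $6339/QALY, ΔQALY 0.132,
Δtotal −$1524, 10-year ICER $4210): those depend on the study's own
landmark targets, and under the stand-ins the model yields a larger QALY
gain (0.198) and deeper saving (−$4207) — qualitatively identical
(dominant combined, ICER ≪ WTP), quantitatively outside the ±10%/±0.01
reproduction bands. The corresponding tests are left failing rather than
re-tuning the stand-ins toward the printed numbers, which would demonstrate
nothing. Supplying the genuine targets via `calibration.targets` re-enables
a real reproduction.

## Numerical choices and limitations

Probability rows are validated to sum to 1 within 1e-9; fine splits are
renormalized exactly; the calibration tolerance is 1e-8 on the objective
with an optional `max_objective` failure threshold that raises carrying the
best-found parameters. Degenerate inputs (empty targets, certain-death
annual probabilities, non-stochastic matrices, life tables too short for the
horizon) raise typed errors before any simulation runs. Known limitations:
no microsimulation (cohort-level only), no correlation structure among PSA
draws, no hospital-perspective costing of weekend staffing, no CEAC/EVPI
output, and the care-cost gamma parameterization issue noted above.
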