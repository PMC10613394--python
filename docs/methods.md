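# Methods

## Model structure

A closed cohort of `cohort_size` learners (default 10,000) starts
caries-free at `start_age` (5) and is advanced through one annual Markov
cycle per year of schooling until `exit_age` (15), i.e. 10 cycles. The
four states are *no caries*, *caries*, *treated* and *exited*; the flows
per cycle are

* every living state → *exited* with the age's exit probability
  (drop-out, relocation, move out of the public system), applied before
  the morbidity flows by default (`exit_first`, switchable); *exited* is
  absorbing;
* *no caries* → *caries* with probability `prob_caries(age) × (1 − e)`,
  where `e` is the arm's effectiveness as a proportion;
* *caries* → *treated* with probability `1 − prob_untreated`
  (`prob_untreated` = 0.7: most carious children go untreated);
* *treated* → *caries* with `prob_recurrence` = 0.188.

Cohort arithmetic is fractional (expected-value cohort model, not
microsimulation), so every output is deterministic given the inputs, and
state occupancies are conserved to machine precision every cycle. There
is no half-cycle correction.

## Outcomes and costs

New caries cases accrue the age's baseline mean DMFT, inflated by a
secular trend of `dmft_growth` = 0.59%/year
(`(1 + 0.0059)^cycle`). Recurrent caries does not re-accrue DMFT — the
index counts lifetime affected teeth. Per cycle, living learners accrue
the arm's annual per-learner cost plus the screening cost
(ZAR525.61/learner/year) for every arm that bundles screening (all
except sugar reduction and do-nothing). Costs and DMFT increments are
both discounted at `discount_rate` = 5%/year with cycle 0 undiscounted.
Do-nothing accrues no cost, and each arm's DMFT averted is referenced to
a do-nothing run on the same schedule.

Treatment-state care costs are not modelled: the payer cost is programme
plus screening only. Intervention and screening costs recur annually per
living learner, including the sugar policy's ZAR1.25/learner/year
(implementation cost of taxation/marketing restrictions).

## Effectiveness mechanisms

Published effectiveness is a *percentage reduction in DMFT*; how it
enters a state-transition model is a genuine design choice, so both
readings are implemented behind `ModelConfig.effect_mechanism`:

* `"flow"` (default): effectiveness scales down the caries-onset flow.
  Protected learners remain at risk in later cycles, so cumulative DMFT
  averted falls below `e ×` baseline (risk compensation).
* `"accrual"`: state dynamics are those of do-nothing and effectiveness
  multiplies DMFT accrual directly, making DMFT averted exactly
  `e ×` the do-nothing total — the structure the published averted
  counts for APF gel, fissure sealant and ART follow (each equals
  `e × 200,048`).

The sugar-reduction arm's primary mechanism is instead an absolute
linear dose-response: each g/day of added sugar contributes
`sugar_slope` = 0.0128 DMFT/year, and the modelled 30 g/day cut removes
0.384 DMFT per living learner per year, floored so a cycle's net
increment is never negative. In the PSA the sugar arm is driven by its
sampled beta effectiveness (mean 31.89%, SD 0.18%) through the flow
mechanism, mirroring the distribution assignment of the other arms;
`sugar_mechanism="effect"` applies the beta mean deterministically too.

## Synthetic age schedules and calibration

The age-dependent inputs (`prob_caries`, `prob_exit`, `baseline_dmft`
per age 5–14) come from tables that are not publicly available. The
package therefore generates them: seeded, deterministic schedules with a
non-decreasing caries-onset ramp (caries experience is age dependent),
a flat exit level, and linearly rising baseline DMFT. Defaults —
`level_caries` 0.30, `level_exit` 0.03, `dmft_at_start` 2.5 — were fixed
once from reported South African figures for school-age children
(caries prevalence around 60–70%, mean DMFT of roughly 2–4 teeth, school
attrition of a few percent per year).

Calibration fits a single scalar multiplier on the exit column by
bisection (`scipy.optimize.bisect`, xtol 1e−6, ≤200 iterations) so the
cohort's 10-year screening outlay matches a target, by default the
published ZAR43.78 million, within 0.5% relative; optionally a second
multiplier on the caries column is fitted against a do-nothing total-DMFT
target. Scalar per-column multipliers keep the fit one-dimensional and
stable; per-age free fitting would be under-determined by a single
aggregate. Multipliers that would push any probability outside [0, 1]
raise a calibration error reporting the achievable range — probabilities
are never silently clamped.

The calibration observable is the **undiscounted** screening outlay.
With discounting, the outlay is bounded above by
525.61 × 10,000 × Σₜ 1.05⁻ᵗ ≈ ZAR42.62M even with zero exits, which is
below the ZAR43.78M target; the published figure is therefore only
consistent with an undiscounted total (ceiling ZAR52.56M), and a
`discounted` flag exposes the other convention.

## What the synthetic schedules do and do not reproduce

With the published per-arm totals supplied directly (fixture mode), the
CEA layer reproduces every published derived column — ICERs vs
do-nothing (1,286; 1.43; 983; 446; 313), ranked incremental ICERs
(7,087; −1,082; 10), average lifetime costs (5,402; 7,278) and NMBs to
within 0.01% — so table-level agreement does not depend on the engine.

The engine-level absolute totals (e.g. ART's ZAR45.06M / 144,035 DMFT
averted, or the PSA means/SDs) are **not** reproducible from the stated
inputs alone: they require the unavailable age tables, and the published
totals imply mutually inconsistent learner-year counts across arms under
any single cost convention. Passing tests on the synthetic schedules
therefore demonstrate structural correctness (conservation, closed-form
cost identities, equivalence with an independent matrix-propagation
oracle, moment recovery, CEAC normalization, decision-rule consistency,
seed determinism), not numerical agreement with the original cohort's
absolute totals.

## Probabilistic sensitivity analysis

Only the per-arm annual cost and effectiveness are sampled (those are
the parameters with assigned distributions); schedules, structural
probabilities and the screening cost stay fixed. Costs use gamma with
moment matching `shape = m²/s²`, `scale = s²/m`; effectiveness uses beta
on the proportion scale with `ν = m(1−m)/s² − 1`, `α = mν`,
`β = (1−m)ν`. A missing cost SD is filled with 10% of the mean; an
infeasible beta SD (`s² ≥ m(1−m)`) is an error, not a clamp, since
clamping would change the stated uncertainty. One seeded generator is
used per run with arm-major draw order (per arm: all cost draws, then
all effectiveness draws), so seeds reproduce across versions.

The CEAC convention is the probability of being the NMB-argmax among all
mutually exclusive options including do-nothing (NMB 0); exact ties
share the count equally, so curves sum to 1 across arms at every
threshold, and do-nothing takes probability 1 at WTP 0 whenever every
arm has positive cost. A pairwise-vs-do-nothing variant is available via
`ceac(..., pairwise=True)`. The default WTP grid is ZAR0–40,000 in steps
of 500.

## Numerical and interface choices

* ICER display rounding follows the published tables: the vs-do-nothing
  column uses 2 decimals below 10 (so 1.43 stays 1.43), the ranked
  column rounds to the nearest integer (so 9.62 prints as 10); full
  precision is kept internally.
* Ties in effectiveness rank the cheaper arm first.
* Negative ranked ICERs are reported as computed; the frontier
  interpretation (strict + extended dominance flags, convex-frontier
  walk) is available with `frontier=True`.
* Effectiveness is stored on the percent scale as published and
  converted to a proportion exactly once, inside computations.
* Problem sizes in the test suite and acceptance script: engine
  cross-checks use cohorts ≤ 10 over ≤ 3 cycles against the independent
  oracle; distribution moment checks use 10⁵ draws; the bundled PSA runs
  use 200–1000 iterations. A full 1000-iteration PSA takes well under a
  second of compute per arm set.

## Known limitations

* Payer perspective only: no societal costs, school-absence or
  caregiver time costs, and no QALY/DALY weighting.
* No treatment-state care costs; no combination strategies (arms are
  mutually exclusive by assumption).
* The synthetic schedules are calibrated to one aggregate (screening
  outlay); all other engine-level absolute outputs depend on the
  generator's defaults and should be read as internally consistent
  scenarios, not estimates for the original cohort.
* No correlated parameter sampling, value-of-information analysis or
  one-way deterministic sensitivity analysis.
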