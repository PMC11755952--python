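# Methods

## Decision problem and model structure

The model compares two policies for managing a severe food-allergic
reaction (anaphylaxis requiring epinephrine) in a Canadian pediatric
cohort entering at age 1 with confirmed food allergy:

- **Immediate ED transfer** — every reaction day routes to the emergency
  department by ambulance, regardless of autoinjector use or symptom
  resolution.
- **Watchful waiting** — after at-home autoinjector use with resolving
  symptoms the child is observed at home; only children without an
  autoinjector (probability 0.094) or with a biphasic recurrence (0.046)
  transfer to the ED, a combined per-reaction transfer probability of
  0.14.

Seven health states are tracked in daily cycles over a 20-year horizon
(7,300 cycles): *no severe reaction*, *watchful-waiting reaction day*,
*ED transfer*, *hospitalization*, *food-allergy death*, *remission*, and
*all-cause death*. Reaction-day states last exactly one cycle; an ED
visit can admit to hospital for one additional day (probability
1.68 × 10⁻³); both death states are absorbing. Remission is absorbing
with respect to food allergy: no further reactions, background mortality
only. Biphasic recurrences are folded into the reaction-day transfer
probability rather than modelled as a 72-hour tunnel — the state diagram
has no tunnel states and the transfer probability is defined by simple
addition of the two fractions.

## Probabilities

All annual probabilities are converted to the daily cycle with the
constant-hazard compound formula `p_day = 1 − (1 − p_year)^(1/365)`; the
year is fixed at 365 days with no calendar anchoring. Key inputs:

| Parameter | Base value | Why it matters |
|---|---|---|
| Annual severe-reaction probability | 0.087 | drives both ED costs avoided and deaths incurred |
| ED transfer probability (watchful waiting) | 0.14 (derived) | splits reaction days between home observation and the ED |
| Hospital admission given ED visit | 1.68 × 10⁻³ | calibrated (see below) |
| In-hospital food-allergy fatality | 4.5 × 10⁻³ per admission | terminal branch of the immediate arm |
| Overall annual food-allergy fatality | 6.9 × 10⁻⁷ | calibration target |
| Watchful-waiting fatality multiplier | 10 (scenarios: 100/500/1000) | the central structural assumption |
| Annual remission probability, ages 1–6 | 0.058 | (1 − 0.058)⁶ ≈ 0.70, i.e. ≈ 29% cumulative remission |

**Hospitalization calibration.** The admission probability is not
observed; it solves `incidence × p_admit × p_fatal_hosp =
p_fatal_overall` under universal ED presentation. The algebraic solution
at the stated inputs is 1.7625 × 10⁻³, while the conventionally used
value is 1.68 × 10⁻³ (a remission- or mortality-adjusted incidence in the
original derivation would explain the gap). The package exposes the
calibration (`calibrate_hospitalization_prob`) but the base case uses the
conventional 1.68 × 10⁻³; the ≈ 5% difference is immaterial because
hospitalization is two orders of magnitude rarer than ED visits.

**Out-of-hospital fatality under watchful waiting.** The multiplier
scales the *overall* fatality target (10 × 6.9 × 10⁻⁷ = 6.9 × 10⁻⁶/yr).
Part of that target is realised in hospital
(`0.087 × 0.14 × 1.68e−3 × 4.5e−3 ≈ 9.2 × 10⁻⁸`); the remainder is
spread over the expected watchful-waiting state-days per person-year
(`365 × p_react_daily × 0.86 ≈ 0.0783`), giving a per-day conditional
probability of 8.70 × 10⁻⁵ and an annualized conditional risk of 0.0313
(reported as 0.031). By construction the recomposition
`q × ww_days + in_hospital` returns the multiplier-scaled target exactly
(tested at 10⁻⁹ relative tolerance). When the transfer probability is 1
the state is unreachable and `q` is defined as 0.

**Competing risks within a day** are resolved fatality-first (the
state-specific fatality claims its mass, all-cause mortality applies to
the remainder, survivors split over non-fatal destinations). At daily
probabilities of 10⁻⁴ and below the ordering changes nothing beyond
rounding; it is used because it keeps every row exactly stochastic, which
is asserted at build time (10⁻⁹ tolerance).

**Background mortality** comes from an age-indexed annual life table
converted to daily probabilities at the cohort's current integer age
(age increments every 365 cycles); it applies from every alive state,
including the one-day reaction states. The bundled table
(`canada_2022_synthetic_life_table.csv`, ages 0–25) is a synthetic
stand-in with plausible pediatric both-sexes values of the correct order
of magnitude (infant ≈ 4 × 10⁻³, childhood ≈ 10⁻⁴, adolescence rising to
≈ 8 × 10⁻⁴); because background mortality is nearly identical across the
two arms it cancels almost exactly in every incremental quantity, which
is why the stand-in suffices. Users can substitute an official table via
`LifeTable.from_csv` / the CLI's `life_table_csv` config key.

## Costs and utilities

All costs are 2022 CAD, healthcare-system perspective in the base case.

- Per-day state costs: annual food-allergy medical costs $1,388/365 in
  the no-reaction state, $569/365 in remission, $1,866 per hospital day.
- Per-entry event costs: a $95 replacement autoinjector on home
  observation days; ambulance ($848) + ED visit ($331) + epinephrine on
  ED days. The epinephrine component is $52.1 in the immediate arm
  ($0.80 in-ED injection + 54% × $95 replacement) and a mixture in the
  watchful-waiting arm ($0.80 for the no-device fraction, $95.80 for the
  biphasic fraction, ≈ $32 expected).
- Societal perspective adds $95 out-of-pocket + $113 productivity loss
  (3.6 h × $31.37) per ED visit, $251 (8 h) per hospitalization, and the
  annual out-of-pocket ($2,577) and indirect ($4,421) food-allergy costs
  as daily shares in the no-reaction state.
- Utilities: 0.92 with food allergy, 0.93 in remission, and a 0.09
  reaction-day decrement applied to each day spent in a reaction state
  (home observation, ED, hospital), floored at zero.

Because the reaction-day states last exactly one cycle, entry flow equals
occupancy and event costs fold into the per-cycle reward vector.
Hospitalization is costed as one day at the daily rate, consistent with
the one-day hospital state; the 2.1-day mean stay enters only the PSA
construction of the daily rate (total-cost draw ÷ length-of-stay draw).
Annual background costs accrue uniformly on every alive pre-remission
day, including reaction days (the overlap is a few dollars over the whole
horizon). Discounting is continuous per cycle, `(1 + r)^(−t/365)` from
day 0, with no half-cycle correction — at one-day cycles the correction
is bounded by half a day of rewards.

## Analyses

- **Base case** — deterministic run of both strategies at point
  estimates; increments, ICER, INMB at $50,000/QALY, and cost per death
  prevented are computed from unrounded deltas.
- **One-way DSA** — each parameter swept across ±20% of its base value,
  except the in-ED epinephrine cost (swept over its logical extremes
  $0.80–$95) and the state utilities (0.74–1.0). Dependent derived
  quantities are re-derived at each bound (varying the biphasic
  probability moves the transfer probability; varying the reaction
  probability rescales the out-of-hospital fatality so the multiplier
  target is preserved). Rows are emitted in tornado order (widest ICER
  range first).
- **PSA** — 1,000 Monte Carlo iterations; independent draws per parameter
  from the assigned distributions (beta for probabilities/utilities,
  gamma as shape–scale for costs, lognormal as meanlog–sdlog for length
  of stay; parameters marked fixed are not sampled). Gamma(100, 8.5) has
  mean 850 ≈ the $848 ambulance cost and Lognormal(0.25, 0.99) mean
  ≈ 2.1 days, fixing the parameterisation conventions. Autoinjector
  possession is sampled and complemented to the no-device probability;
  the hospital daily rate is a ratio of a total-cost and a
  length-of-stay draw; the reaction disutility draw is clamped to the
  utility draw so reaction-day utility stays non-negative (a rare
  tail event of Beta(0.17, 1.7)). Point estimates use the ratio of mean
  deltas (ICER of means). The CEAC reports the fraction of iterations
  with positive INMB per willingness-to-pay value.
- **Scenarios** — 0% and 3% discounting, societal perspective,
  100/500/1000× fatality multipliers, and start age 0, each summarised
  over 1,000 PSA iterations with independent child seeds spawned from the
  run seed.

## Implementation notes

The cohort engine has two equivalent paths: a readable single-cohort
trace (occupancy matrix, 7,301 × 7) and a fused batched
propagate-and-accumulate used by the PSA and scenario analyses, which
advances all iterations simultaneously and accumulates discounted rewards
on the fly without storing traces. The two are tested for agreement at
10⁻¹² relative tolerance. An individual-level microsimulation oracle
re-implements the transition rules by direct random draws and agrees with
the cohort trace within three binomial standard errors at 50,000
individuals over a one-year horizon.

Default problem sizes — 7,300 cycles, 1,000 PSA iterations, seven
scenarios at 1,000 iterations each — run in well under a minute in total;
unit and property tests use 2-year horizons and smaller iteration counts
where the full horizon adds nothing to the property under test.

## What the synthetic generators do and do not cover

`synthetic_parameters` draws valid parameter sets with the same
distributional structure as the probabilistic analysis, and
`synthetic_life_table` produces geometric mortality curves; they exercise
every code path (including degenerate zero-mortality and zero-event
configurations) but encode no correlation between parameters, no
individual-level heterogeneity (comorbidities, reaction history, repeat
reactions within a day), and no secular trends. Passing tests therefore
demonstrate internal correctness of the model arithmetic under the stated
assumptions, not external validity of those assumptions.

## Known limitations

- The fatality multiplier for watchful waiting is a structural assumption
  (no empirical estimate exists); conclusions at 500–1000× reverse.
- Hospitalization risk is not increased under watchful waiting, matching
  the model's assumption set; hospitalization is rare enough that this
  barely moves totals.
- The bundled life table is a synthetic stand-in (see above).
- No correlation structure in the PSA; no value-of-information analysis;
  no travel-time costs in the societal perspective.
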