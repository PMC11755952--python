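# wwcea

A Markov cohort cost-effectiveness model of **watchful waiting** versus
**immediate emergency-department (ED) transfer** after epinephrine
autoinjector (EAI) use for severe food-allergic reactions in children.

Pediatric anaphylaxis guidance long required ED transfer after every EAI
use, even when symptoms resolved promptly. This package implements a
health-economic decision model for the Canadian setting that asks what
that universal requirement buys: a cohort of one-year-olds with food
allergy is propagated in daily cycles over a 20-year horizon through seven
health states — no severe reaction, at-home watchful waiting after EAI
use, ED transfer, hospitalization, food-allergy death, food-allergy
remission, and all-cause death — under the two management strategies, and
the incremental costs (2022 CAD) and quality-adjusted life years (QALYs)
are compared.

## Model

Under **immediate ED transfer**, every severe reaction day routes to the
ED (ambulance + ED visit + epinephrine bundle), with a calibrated
admission probability and in-hospital fatality risk. Under **watchful
waiting**, only the fraction without an EAI (9.4%) or with a biphasic
recurrence (4.6%) transfers — 14% in total — while the remaining 86%
observe at home with an assumed tenfold increase in the overall annual
food-allergy fatality (6.9 × 10⁻⁶ vs 6.9 × 10⁻⁷), realised as an
out-of-hospital fatality risk conditional on occupying the home
observation state.

Outcomes are summarised as

- **ICER** = ΔC / ΔE, the incremental cost per QALY gained through
  immediate transfer (deltas are watchful waiting minus immediate ED), and
- **INMB** = λ·ΔE − ΔC at willingness-to-pay λ = $50,000/QALY, so that the
  cost savings of watchful waiting enter positively.

Both costs and QALYs are discounted at 1.5%/year. Uncertainty is handled
by one-way deterministic sensitivity analysis (tornado), probabilistic
sensitivity analysis (Monte Carlo over beta/gamma/lognormal parameter
distributions, cost-effectiveness plane and acceptability curve), and a
scenario battery (0%/3% discounting, societal perspective, 100/500/1000×
fatality multipliers, start age 0). See `docs/methods.md` for the full
specification of states, rewards and numerical conventions.

## Worked example

```sh
$ wwcea base --out out/
Watchful waiting : $20,675  15.9306 QALYs
Immediate ED     : $21,829  15.9313 QALYs
Incremental cost : $-1,154
Incremental QALY : -7.302e-04
ICER             : $1,579,920/QALY
INMB             : $1,117 at WTP $50,000/QALY
Cost per death prevented: $12,543,790
```

Reading: over 20 years a child managed by watchful waiting costs the
system about $1,154 less and loses about 0.0007 QALYs (driven by a
9.2 × 10⁻⁵ higher cumulative food-allergy death risk). Buying that QALY
back through universal immediate transfer costs ≈ $1.6 million per QALY —
far above any conventional willingness-to-pay threshold — or ≈ $12.5
million per death prevented, so watchful waiting is cost-effective
(positive INMB). The same conclusion survives the probabilistic analysis:

```sh
$ wwcea psa --n 200 --seed 42 --out out/
200 iterations, seed 42
Mean incremental cost : $-1,128
Mean incremental QALY : -7.682e-04
ICER (of means)       : $1,468,762/QALY
Cost-effective at WTP $50,000: 100.0% of iterations
```

Other subcommands: `wwcea dsa` (tornado CSV), `wwcea ceac`
(acceptability curve), `wwcea scenarios` (scenario table). All accept
`--set group.field=value` overrides, `--config` YAML files, and write
full-precision CSV/JSON artifacts plus a `run_metadata.json` that
suffices to reproduce the run bit-for-bit. The same functionality is
available from Python:

```python
from wwcea import default_parameters, bundled_life_table, base_case

cmp_ = base_case(default_parameters(), bundled_life_table())
print(cmp_.icer, cmp_.inmb)
```

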