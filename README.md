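# medmultiverse

Multiverse analysis for single-mediator models.

A mediation analysis — estimating how much of the effect of a determinant
X on an outcome Y runs through a mediator M — rests on a chain of
defensible-but-arbitrary analysis decisions: determinant coding, confounder
set and selection strategy, moderator stratification, determinant–mediator
interaction, and the criterion that declares "mediation". Reporting one
specification hides how much the conclusion depends on those choices.
`medmultiverse` declares the decisions as a grid, runs the complete
mediation analysis in *every* combination (every universe), and summarizes
the robustness of the direct, indirect and total effect estimates with
specification curves.

For whom: epidemiologists and prevention researchers who want to check a
published (or planned) single-mediator result against all reasonable
specifications of it.

## The model

Per universe, the classic three linear regressions (OLS, classical SEs):

```
Y = i1 + c·X          + controls + e1      (total effect)
M = i2 + a·X          + controls + e2      (mediator model)
Y = i3 + c'·X + b·M   + controls + e3      (outcome model)
```

Universes without determinant–mediator interaction report the indirect
effect ab and direct effect c′. Universes with an X·M term (coefficient h)
report natural effects for a contrast x0 → x1:

```
PNDE = (c' + h·(μ0 + a·x0))·(x1−x0)     PNIE = (b + h·x0)·a·(x1−x0)
TNDE = (c' + h·(μ0 + a·x1))·(x1−x0)     TNIE = (b + h·x1)·a·(x1−x0)
```

with PNDE + TNIE = TNDE + PNIE = total effect. All effects get Monte Carlo
percentile confidence intervals (coefficient vectors sampled from their
estimated sampling distribution, 20,000 draws by default, seeded and
reproducible). Each universe is judged by two mediation criteria: the
original-study style rule (causal steps + proportion mediated ≥ 20%) and
the indirect-effect confidence interval.

The built-in grid mirrors a worked example from a cohort of older women
(percent weight change → fat mass → hip bone mineral density): 3
determinant codings × 2 confounder sets × 2 selection strategies (a priori
vs ≥ 10% change-in-estimate) × 3 age-moderation options × 3 interaction
options = 108 indirect/direct specifications, collapsing to 36 distinct
total-effect specifications. The cohort data are access-restricted, so the
package ships a seeded synthetic generator with the same structure; see
`docs/methods.md` for what it does and does not emulate.

## Worked example

```python
import medmultiverse as mv

data = mv.generate(mv.lasa_like(seed=1))          # synthetic cohort, n = 264
points = mv.worked_example_decision_points()              # the 108-universe grid
universes = mv.enumerate_universes(points)
config = mv.default_config(seed=1)
result = mv.run_multiverse(data, universes, config, points)

ind = result.rows("indirect")
orig = ind[ind["is_original"]].iloc[0]
summary = mv.summarize_verdicts(result)

curve = mv.build_curve(result, "indirect")
mv.render_curve(curve, "curve_indirect.svg")
```

Output for this seed:

```
universes: 108; indirect rows: 108; total rows: 36
original indirect (ab): 1.57 mg/cm^2  [0.91, 2.36]  significant=True
indirect range: [-47.0, 101.8] mg/cm^2
mediated, original criteria: 34.3%  (37/108)
mediated, indirect-effect CI: 63.0%  (68/108)
direct effects negative: 58.3%; significant: 5.6%
total effects positive: 80.6%; significant: 36.1%
```

Reading: the original specification (continuous weight change, full
a-priori confounder set, all ages, no interaction) estimates that a one
percentage-point weight increase raises BMD by ≈1.6 mg/cm² through fat
mass, and the Monte Carlo interval excludes zero. Across all 108
specifications the indirect estimate varies widely (the extreme values come
from low-powered decreased-weight and old-old strata), and the
interval criterion declares mediation more often than the causal-steps +
proportion rule — inconsistent-mediation universes (positive indirect,
negative direct, washed-out total effect) fail the causal-steps check while
their indirect interval still excludes zero. The specification curve
(`curve_indirect.svg`) shows the ranked estimates on top and the decision
combination behind each estimate below, with the original specification
highlighted.

A shell interface wraps the same pipeline:

```
medmultiverse simulate --out cohort.csv --seed 1
medmultiverse run --data cohort.csv --out results/ --seed 1
medmultiverse enumerate
medmultiverse summarize --data results/results.csv
medmultiverse curve --data results/results.csv --effect direct
```

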