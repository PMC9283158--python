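# Methods

## The problem

A single-mediator analysis asks how much of the effect of a determinant X
on an outcome Y travels through an intermediate M. Every concrete analysis,
however, rests on a chain of defensible-but-arbitrary decisions: how to code
the determinant, which confounders to adjust for and how to choose them,
whether to stratify by a moderator, whether to allow determinant–mediator
interaction, and which criterion declares "mediation". `medmultiverse`
makes those decisions explicit as a grid of decision points, runs the full
mediation analysis in every cell of the grid (every *universe*), and
summarizes how robust the direct, indirect and total effect estimates are
across the grid.

The package's worked example is an aging-cohort setting: percent change in
body weight since age 25 (X, %), total-body fat mass (M, kg) and hip bone
mineral density (Y, mg/cm²) in older women (n = 264), with an
anthropometry/lifestyle/disease/medication confounder panel, a hormonal
block of ambiguous causal status, and age (old-old ≥ 75) as a moderator.
The real cohort data are access-restricted, so the package ships a seeded
synthetic generator with that structure instead (see below).

## Mediation model

Three linear regressions, all fitted by OLS with classical homoskedastic
standard errors and t-reference tests:

    Y = i1 + c·X            + controls + e1      (total effect)
    M = i2 + a·X            + controls + e2      (mediator model)
    Y = i3 + c'·X + b·M     + controls + e3      (outcome model)

Traditional quantities: indirect effect ab (product of coefficients) or
c − c′ (difference of coefficients); these coincide algebraically whenever
the outcome equation has no X·M term and the total- and direct-effect
equations share one covariate
set. Proportion mediated is 100·(indirect)/c, flagged undefined when
|c| < 1e-10; under inconsistent mediation (opposite-signed direct and
indirect effects) it can exceed 100% and is returned as-is with a flag.

With an X·M interaction term (coefficient h; the symbol is ours — the
interaction is standard but carries no conventional letter) the
potential-outcome natural effects for a contrast x0 → x1 are computed from
the fitted coefficients:

    PNDE = (c' + h·(μ0 + a·x0))·(x1 − x0)
    TNDE = (c' + h·(μ0 + a·x1))·(x1 − x0)
    PNIE = (b + h·x0)·a·(x1 − x0)
    TNIE = (b + h·x1)·a·(x1 − x0)

where μ0 is the mediator-model prediction at X = 0 with covariates held at
the evaluation profile. Both decompositions PNDE + TNIE = TNDE + PNIE =
total hold identically, and h = 0 collapses all four to c′ and
a·b·(x1 − x0). The estimator is purely regression-based; a brute-force
potential-outcome simulation (drawing mediator residuals and averaging
cross-world outcome means) exists only in the test suite, as an independent
oracle for the closed forms.

**Covariate profile.** Natural effects of the linear model depend on the
covariate profile only through the h·μ0 term. The default profile is the
sample mean of each continuous covariate over the universe's complete-case
analysis subset and the reference level (0) for binary/dummy covariates,
detected automatically by value set. The profile is recorded in the output.

**Determinant contrast.** Continuous coding uses x0 = 0 (no weight change)
to x1 = 1 (one percentage-point increase); each categorical coding is a
0/1 contrast of an index class against stable weight.

## Monte Carlo confidence intervals

Indirect effects are products of coefficients, so their sampling
distributions are skewed. The interval used everywhere is the Monte Carlo
percentile interval: draw coefficient vectors from a multivariate normal
centred at the estimates with the estimated coefficient covariance
(mediator-model and outcome-model blocks drawn independently, since they
come from separate regressions), push each draw through the effect formula,
and take the (1−level)/2 and 1−(1−level)/2 empirical quantiles. Defaults:
20,000 draws (percentile stability to roughly two decimals at
worked-example scale), level 0.95, a recorded seed; identical seed and
inputs reproduce the interval bit for bit. A minimum of 1,000 draws is
enforced. Within one universe the indirect and direct effects are evaluated
on the same draw matrix, so their decomposition is coherent draw by draw.

## Variable-centric decisions

**Edwards–Nunnally reliable change.** The pretest (lowest weight since age
25) is regressed toward the sample mean by the scale reliability r
(Cronbach's alpha, default 0.822) and surrounded by two standard errors of
measurement: adjusted ± 2·sd_pre·√(1 − r). Posttests above/below the band
are increased/decreased; the boundary is classified stable (conservative:
change must exceed the band). Pre mean/sd default to the analysis sample
and can be overridden in config. As r → 1 the band collapses to the
pretest. The ±2·SEM band is one of several published variants of the
index; it is the one implemented here.

**Change-in-estimate confounder selection.** Each candidate is evaluated
one at a time against the unadjusted mediator and outcome models: refit
with the candidate added, compute 100·(adjusted − unadjusted)/unadjusted
for the a, b and c′ paths, and select candidates whose maximum absolute
change meets the threshold (default 10%, inclusive). The total-effect (c)
path does not participate. Both fits for a candidate use the complete cases
of that candidate's own variable set, so the comparison is not an artifact
of differential missingness. Paths with near-zero unadjusted estimates are
skipped with a warning. Selection is one-at-a-time by design — stepwise or
joint strategies are themselves researcher degrees of freedom and would
belong in a user's own multiverse.

**Simple slopes.** Age moderation adds X·Z terms to every equation where X
appears and an M·Z term to the outcome equation (Z = old-old indicator),
then reads off stratum-specific paths as linear combinations, e.g.
a(z) = a + z·a_xz, with SEs from the linear-combination variance. Stratum
universes therefore reuse the pooled interacted fit rather than refitting
on subsets. The total-effect equation is also moderated, so each stratum
reports a stratum-specific total effect; this is a deliberate consistency
choice and is visible in the output. With no extra covariates the pooled
interacted model is saturated in Z and reproduces stratified refits
exactly; with non-interacted covariates the equivalence is approximate.

## The multiverse engine

Decision points are generic (name + ordered options); the built-in grid is

| point | options |
|---|---|
| determinant | continuous, increased-vs-stable, decreased-vs-stable |
| confounder set | full panel, panel without hormonal block |
| confounder consideration | a priori, ≥ 10% change-in-estimate |
| age moderation | all ages, < 75, ≥ 75 |
| X·M interaction | none (ab, c′), pure natural effects, total natural effects |

for 3·2·2·3·3 = 108 universes, enumerated in lexicographic order with the
all-first-options universe flagged as the original specification. The
interaction decision never reaches the total-effect equation, so the grid
holds 3·2·2·3 = 36 distinct total-effect specifications; the engine emits
one total-effect row per distinct resolved total-effect model.

Change-in-estimate selection is executed once per (determinant coding,
candidate set, moderation option) and cached; it does not depend on
interaction handling. In stratified universes the percent changes are
computed on the stratum simple slopes.

Redundancy: universes whose resolved specifications (determinant coding,
covariate set, moderation, interaction, estimand) coincide — e.g. when
selection returns exactly the a-priori set — are collapsed to one canonical
universe; estimates are computed once and reported for every member with a
redundancy flag.

Per universe, analysis uses complete cases on that universe's variable set
(missingness in the emulated setting is low, 0–7%, and is handled by
listwise deletion only — no imputation). Failures inside a universe
(e.g. a degenerate design in a tiny stratum) are recorded in that
universe's `warning` column and never abort the run.

**Verdicts.** Two mediation criteria are computed for every universe:

- *Original-study criteria*: the four-condition causal-steps rule — c, a
  and b each significant (p < alpha, default 0.05) and |direct| < |c| —
  AND proportion mediated ≥ 20% (configurable). In natural-effect
  universes the universe's own indirect/direct estimates feed the
  proportion and attenuation checks, and b is the stratum-level mediator
  main effect; in no-interaction universes this is exactly the classic
  rule. An undefined proportion fails the criterion.
- *Interval criterion*: the Monte Carlo CI of the universe's indirect
  effect excludes zero.

The interval criterion is insensitive to a non-significant total effect
(relevant under inconsistent mediation) and to the proportion threshold, so
it typically declares mediation in at least as many universes — the
divergence mechanism the summaries expose.

**Identity bookkeeping.** ab = c − c′ is asserted (1e-8) in every universe
where it is an OLS theorem: no X·M term and no moderation. With an M·Z
term in the outcome equation the omitted-block projection is no longer a·b,
so the identity provably fails in finite samples; those universes carry
`ab_identity_applicable = False` rather than a spuriously widened
tolerance.

## Synthetic generator

The generator emulates the worked example's variable roster and scales:
confounders first (height, age, smoking, alcohol, walking, sports, COPD,
stroke, rheumatoid arthritis, diabetes, corticosteroid use, estrogen use,
with realistic marginals); X as a linear function of its confounders plus
noise (mean 10%, residual sd 13.5 — raw lowest/current weights are emitted
consistently with X so reliable-change coding works and all three change
classes are populated at n = 264); M = a·X + confounders + noise (≈25 kg,
residual sd 5); Y = c′·X + b·M + h·X·M + confounders + noise (≈800 mg/cm²,
residual sd 80). Age ≥ 75 shifts a by −0.08 and b by −3, so stratified
universes genuinely differ. Default effects a = 0.25 kg/%, b = 13 mg/cm²
per kg, c′ = −0.5 give an indirect effect near 3 mg/cm² per percentage
point with roughly 80% power in the original specification, so a full run
shows a realistic mix of significant and non-significant universes
(decreased-weight contrasts and old-old strata lose power, mirroring the
structure of the emulated study).

The hormonal block (ln-SHBG, ln-PTH, 25(OH)D, IGF-1, albumin) is generated
*downstream of fat mass* and carries part of the fat-mass→BMD effect
(`true_b` is the total mediator effect; the share routed through the
hormones is subtracted from the direct coefficient). Adjusting the outcome
model for the block therefore attenuates b — exactly the causal ambiguity
that motivates offering a reduced confounder set.

Missingness is completely at random, column-wise (default 2%, capped at 7%
to stay in the low-missingness regime that justifies complete-case
analysis); the determinant column is kept fully observed. The generator is
bit-reproducible under its seed. `true_natural_effects` returns the
effects implied by the generating coefficients with confounders at their
means and the moderator at its prevalence (exact when moderator shifts are
zero; the conditional-at-means target otherwise).

What the generator does **not** emulate: real marginal distributions and
their skew, informative missingness, measurement error beyond the
reliable-change construction, and any non-linearity. Passing tests
demonstrate correctness of the machinery under a linear,
MCAR, known-truth world — not that any real dataset satisfies the
no-unmeasured-confounding assumptions the estimands require.

## Numerical choices

- OLS is solved through a numerically stable decomposition (statsmodels'
  pinv path) and is required by tests to match explicit normal equations to
  1e-8 on well-conditioned data; rank deficiency is detected beforehand via
  pivoted QR so the error can name a dependent column.
- Covariance matrices entering the Monte Carlo sampler are checked
  symmetric PSD (eigenvalue tolerance 1e-10 relative).
- Per-universe Monte Carlo seeds are derived from the run seed and the
  canonical universe id through `numpy.random.SeedSequence`, so the full
  run is deterministic end to end and independent of execution order.
- Results CSVs serialize floats at six significant digits, making reruns
  byte-identical and testable; SVG rendering pins the hash salt and strips
  the date for the same reason.
- Test problem sizes: recovery tests at n = 20,000; interval calibration at
  n = 500 over 500 replicates; oracle comparisons at 10⁶ draws. These are
  the sizes at which the assertions' tolerances (3 SE bands, [92.5, 97.5]%
  coverage) are meaningful.

## Known limitations

- Homoskedastic SEs only; no robust or clustered variants.
- Linear models only: no GLM links, no controlled direct effects, no
  sensitivity analysis for unmeasured confounding, no bootstrap or
  distribution-of-the-product intervals (the interval interface is a single
  function and is extensible).
- No multiple-testing adjustment across universes; the intended reading of
  a multiverse is the pattern of estimates, not per-universe hypothesis
  tests, and the summaries report raw per-universe inference.
- Mean/median summary inference over the specification curve is
  deliberately not offered; the accuracy of such summaries is an open
  methodological question.
- The proportion-mediated definition (indirect/c) and the inclusion of a
  significant total effect in the causal-steps rule are documented
  operationalizations of criteria whose historical usage varies.
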