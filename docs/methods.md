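# Methods

## The models

Two individual-tree mixed models cover the trial series. For seedling trials,

    y = X b + Z1 a + Z2 f + Z3 r + Z4 b + Z5 p + e

with `a ~ N(0, A σ_A²)` the additive genetic effects over all pedigree
members (A the numerator relationship matrix), `f` full-sib family effects
(one quarter of the dominance variance), `r` replicate, `b` incomplete-block
within replicate and `p` row-plot effects, and i.i.d. residuals. The only
fixed effect is the overall mean. For clonally replicated trials the plot
term is dropped (single-tree plots) and a clone-within-family term `c`
(epistasis plus three quarters of the dominance) is added; ramets of one
clone share a single column of the additive and clone incidences, which
keeps A non-singular at the genotype level.

Heritabilities use the phenotypic variance in the narrow sense — design
variances (replicate, block, plot) are excluded from the denominator:

    h² = σ_A² / (σ_A² + σ_NA² + σ_e²),    H² = (σ_A² + σ_NA²) / (σ_A² + σ_NA² + σ_e²)

with `σ_NA² = σ_f²` in seedling fits and `σ_f² + σ_c²` in clonal fits. No
rescaling of `σ_f²` to total dominance is applied: the ratios use the raw
fitted components. Standard errors come from the delta method on the
REML sampling covariance (inverse average-information matrix).

Bivariate fits follow a reduced trait-pair model: fixed trait means, a
replicate effect per trait, a genetic effect with unstructured 2×2
between-trait covariance (pedigree-structured additive in seedling data,
independent total-genotypic clone effects in clonal data), and a 2×2
residual covariance across the two observations of a tree. The genetic
correlation is `r_G = σ_G12/(σ_G1 σ_G2)`; the phenotypic correlation uses
genetic-plus-residual (co)variances. Type-B correlations treat one trait at
two sites as two traits over the joint pedigree with zero residual
covariance (no tree grows at both sites). Breeding-value agreement between
trials is a Pearson correlation over shared parents or clones; survival is
summarised as family/clone mean proportions with a nonparametric bootstrap
over those units (default 1,000 draws) for its correlations, rather than a
threshold model at the individual-tree level.

## Pedigree machinery

A is built by the tabular recursion; its inverse is assembled directly from
pedigree rules with Mendelian-sampling variances `d_i = 1 − (a_ss + a_dd)/4`
(unknown parents contribute zero), so inbreeding is handled exactly even
though the simulated designs are non-inbred. `log|A|` is the sum of
`log d_i`, which the REML likelihood needs once per fit. Polymix sires are
coded unknown: offspring of one dam are half sibs (`a = 0.25`).

## REML

Variance components maximise the restricted likelihood

    -2 logL = log|R| + log|G| + log|C| + y'Py

evaluated through the variance-scale mixed-model equations with coefficient
matrix `C = W'R⁻¹W + G⁻¹`; `C⁻¹` directly provides `Var(û − u)` (PEVs) and
the EM traces. Iteration starts with two EM steps (monotone, robust far from
the optimum) and then takes average-information (AI) steps. Because AI is
only an approximation of the information matrix and can be indefinite far
from the optimum, each step is safeguarded: Levenberg-style damping toward a
scaled gradient step, step halving, and an EM fallback. Variances are kept
above a floor of `1e-10 · var(y)`; a variance pinned below `1e-8 · var(y)`
is handled with an active set — frozen while the boundary gradient points
outward, released otherwise. Convergence requires a relative likelihood
change below the tolerance (default `1e-6`, maximum 200 iterations), a
negligible Newton decrement over the interior parameters, and no pinned
variance whose release would still buy a non-trivial likelihood gain. After
convergence, terms pinned at zero are dropped and the model refit; they are
reported as "no estimate" with a zero component, mirroring blank cells in
published tables. Between-trait covariances are clamped inside the PSD cone
(|correlation| ≤ 0.999); a clamp that remains active at convergence simply
reports a correlation at the clamp, which is the correct reading of
degenerate inputs such as duplicated traits. Starting values partition the
phenotypic variance equally across terms.

The univariate solver and the bivariate extension share one engine; the
dense-GLS identity (`β̂ = (X'V⁻¹X)⁻¹X'V⁻¹y`, `û = GZ'V⁻¹(y − Xβ̂)`), the
dense REML log-likelihood, Wright's path-counting coefficients and the
balanced half-sib ANOVA estimator (`σ_A² = 4 σ_dam²`) serve as independent
oracles in the test suite, never as the implementation.

## Phenology conversion

The day of year (DoY) of a phenology event is the first assessment at which
the critical score (budbreak 3, senescence 7) is recorded exactly, otherwise
the linear interpolation within the first adjacent pair of assessments whose
scores bracket it; with exactly two bracketing points a regression through
them is the same interpolation, so only the two-point form is implemented.
Trees never reaching or bracketing the critical score are missing.
Interpolated values stay fractional internally; rounding to whole days
happens only in reports. Non-monotone trajectories (e.g. frost-regressed
buds) are not repaired — the first crossing wins.

## The synthetic trial generator

The generator reproduces the statistical structure the estimators assume,
with defaults set to the study conditions of the published trial series:

- **Mating**: 61 dams × 61 sires, 100 full-sib crosses in a partial
  factorial with at most two crosses per parent, 60 polymix (half-sib)
  dams. Trials subsample these families (e.g. 37 HS + 83 FS with 560 clones
  for the large clonal trial; 33 HS + 50 FS seedling families for trial 02).
- **Layouts**: `R×B×T×P` alpha geometries exactly as published (6×10×9×3 =
  1,620 trees; 9×24×24×1 = 5,184; 9×8×6×1 = 432), with simple randomisation
  of treatments to alpha blocks and flagged filler replications in surplus
  cells — design-efficiency optimisation is irrelevant for estimator
  testing.
- **Genetics**: breeding values by gene dropping (founder draws plus
  Mendelian-sampling deviations scaled by `1 − (a_ss + a_dd)/4`), which is
  O(n), exact for any pedigree, and independent of the tabular A it is used
  to test. Family and clone effects are i.i.d.; all genetic strata share a
  configurable between-trait correlation matrix. Because strata mix by
  geometric means, the total-genetic correlation is slightly below the
  per-stratum value when variance proportions differ across traits; the
  recovery-study configuration aligns the proportions so the nominal value
  is exact, and `implied_total_genetic_corr` computes the implied value for
  any other configuration.
- **Trait conditions**: phenology means per trial (budbreak 128/135/135,
  senescence 267/268/273 DoY), budbreak phenotypic SD 2.8 d and senescence
  SD 7 d, with heritability fractions set to the published per-trial
  estimates (e.g. budbreak `h² = 0.46` seedling trial, `0.37/H² = 0.46`
  large clonal trial; senescence additive variance zero in the small
  high-elevation trial, which reproduces its "no estimate" behaviour).
  Design-effect fractions (replicate/block/plot around 4% of the phenotypic
  variance each) are plausible round figures; design effects are drawn
  centred within a trial (deviation coding), so trial means are not
  confounded with a handful of replicate draws.
- **Scores**: a tree's ordinal score at assessment `d` is the nearest stage
  of a linear development `critical + rate·(d − D)` crossing the critical
  stage at the latent DoY `D`, with budbreak at 0.7 and senescence at 0.25
  stages/day on the trials' real assessment calendars. These rates keep the
  exact-score window within one assessment interval, making the conversion
  rule nearly unbiased. Coarse fall calendars and the short ordinal scale
  above the senescence critical stage still shift and truncate the measured
  distribution slightly, so the generator places the latent mean by
  deterministic quadrature (`calibrated_latent_mean`) such that the
  *measured* trial mean equals the configured target — the published trial
  means are means of measured values, so this is the faithful emulation.
- **Survival**: Bernoulli with a logistic link on standardised total
  genetic values (positive slope on senescence DoY, negative on budbreak),
  matching the sign structure of the published survival correlations.

What the generator does not emulate: spatial autocorrelation and microsite
gradients, climate-driven phenology (heat sums), browsing damage,
observer error in scoring beyond stage rounding, and mortality-by-design
confounding. Passing tests therefore show that the estimators recover the
parameters of the assumed model at realistic scale and noise — not that the
model is adequate for any particular field data set.

## Problem sizes and tolerances in the checks

The acceptance suite uses the published trial geometries directly (1,620 to
5,184 trees per replicate dataset). Monte-Carlo checks compare means over
replicates to truth within two Monte-Carlo standard errors: 4–6 replicates
for the single-trial heritability and correlation checks (whose per-replicate
sampling SDs, ~0.03–0.12, are of the same order as the published standard
errors), and 30 replicates for the recovery study at the large clonal
geometry (true `h² = 0.2`, `H² = 0.3`, `r_G = 0.6`). Trial-mean DoY checks
average six generator replicates before rounding to the nearest day. Oracle
equivalences are exact-numerics checks: MME vs dense GLS at `1e-6`,
rule-built A-inverse vs dense inversion at `1e-8`, REML vs balanced
half-sib ANOVA at `1e-4` relative (fit tolerance `1e-12`). Delta-method SEs
are validated against a 500-draw parametric bootstrap at 25% relative. The
acceptance script mirrors these computations at slightly reduced replicate
counts and records the size used with every value.

## Known limitations

- Dense Cholesky of the MME coefficient matrix bounds practical problem
  size to a few thousand genotypes per trial — ample here, but a supernodal
  sparse factorisation would be needed for much larger pedigrees.
- In clonal fits the additive and clone terms share an incidence and are
  separated only by pedigree covariances; their individual components are
  weakly identified in small trials (boundary estimates are common, as in
  the published tables), even though their sum and `H²` are stable.
- The bivariate clonal model treats clones as genetically independent, as
  in the published analysis; family covariances between clones are not
  modelled and slightly inflate the residual.
- Survival is analysed only at family/clone-mean level; no individual-tree
  threshold model is provided.
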