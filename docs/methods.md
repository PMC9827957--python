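# Methods

`evoflor` implements a quantitative-genetic analysis of three-dimensional
blossom morphology in *Dalechampia*: estimation of the mean-scaled additive
genetic covariance matrix **G** from a block-diallel breeding design,
Hansen–Houle evolvability statistics over phenotype space, and comparison of
standing evolvability with among-population and among-species divergence.
This note documents the models, the estimation machinery, the defaults and
their rationale, and what the synthetic-data generator does and does not
emulate.

## Traits and scaling

The three traits are gland–anther distance (GAD), gland–stigma distance
(GSD) and anther–stigma distance (ASD, functional herkogamy), measured in
mm on individual blossoms.  All variance components are *mean-scaled*:
traits are divided by their sample means before fitting, so variances are
dimensionless proportions of the squared trait mean (Houle's I_A), reported
×100 as percentages.  A diagonal element of 6.6 therefore means an expected
6.6% proportional response to one generation of unit-strength selection on
that trait.  Mean-scaling is applied *before* fitting rather than post hoc
to variance components; this keeps every component of the fitted model in
evolvability units.

## The animal model

Each record (trait *i*, plant *j*, measurement date *k*, blossom *l*)
follows

    z_ijkl = mu_i + a_ij + b_ij + d_ik + q_ijkl

with breeding values **a** ~ N(0, **G** ⊗ **A**), non-genetic plant effects
**b** ~ N(0, **B**), date effects **d** ~ N(0, **D**_date), and blossom
residuals **q** ~ N(0, **Q**).  **A** is the additive relationship matrix
from the pedigree, built by the tabular recursion with selfing handled
through the inbreeding term (one selfing generation gives a diagonal entry
of 1.5).  Dates get their own k×k covariance; dates with a single
observation are retained and shrunk.  Missing trait values are handled by
data augmentation inside the sampler.  Dominance, maternal and reciprocal
effects are not modelled.

### Sampler

The posterior is sampled by a partially collapsed Gibbs sampler:

* `mu`, the date effects, **D**_date and **Q** have standard conjugate
  updates (Gaussian and inverse-Wishart).
* **G** and **B** are confounded through the likelihood — both act at the
  plant level — and conjugate Gibbs moves them along the "allocation ridge"
  (G + B roughly constant) so slowly that chains of 10^5 iterations stay
  near their starting allocation.  They are therefore updated from their
  *collapsed* conditional with the breeding values and plant effects
  integrated out.  Records are padded by data augmentation to a common
  count *m* per phenotyped plant (the all-missing padding rows carry no
  information, so the observed-data posterior is unchanged); the plant-mean
  residuals, rotated into the eigenbasis of the phenotyped block of **A**,
  are then independent with covariance `lam_j G + B + Q/m`, which makes the
  marginal likelihood cheap to evaluate.  The move combines univariate
  slice scans over log-Cholesky parameters, element-wise "trade" slices
  (G + dE, B − dE) that run exactly along the allocation ridge, and
  adaptive random-walk Metropolis proposals with a covariance learned by
  diminishing adaptation.
* Immediately afterwards the breeding values and plant effects are redrawn
  *exactly* from their joint Gaussian conditional (per eigen-coordinate for
  the phenotyped block; non-phenotyped pedigree members by the usual
  pedigree conditional), which is what makes the collapsed move valid.

The sampler was validated against an independent oracle: for a univariate
diallel the full posterior of the three variance components was computed by
direct grid integration of the marginal likelihood (location effects and
the grand mean integrated analytically), and the sampler's posterior means
and 95% intervals match it; a large-sample concentration test (5000
eigen-coordinates) recovers a known (G, B) pair to within Monte-Carlo
error.  Effective sample sizes at the default design are roughly 0.05–0.3
per iteration for G elements.

### Priors

The source analysis this package re-implements does not state its priors, so they are
explicit configuration here.  The default is inverse-Wishart with k+2
degrees of freedom and diagonal scale `phenotypic variance / 4` for each of
the four components — a proper, weakly informative prior whose mean is an
equal split of the phenotypic variance, carrying roughly one
pseudo-observation of weight.  Near-zero-scale IW(k+1, ·) priors were tried
first and rejected: they place an improper-like spike at zero variance, and
because the diallel likelihood is nearly flat along the G/B allocation
ridge, that spike drags the posterior to corners (all plant-level variance
assigned to one component) and destroys the frequentist calibration of the
credible intervals in simulation.  Both the degrees of freedom and the
per-component scale matrices can be overridden via `ModelSpec`.

### Chain defaults

Production default: 75,000 iterations, 25,000 burn-in, thinning 50
(≈1000 retained draws).  The test suite and worked examples use shorter
chains (typically 5,000–8,000 iterations with 1,500–3,000 burn-in),
which the collapsed sampler's mixing makes sufficient for stable posterior
summaries at the canonical design size; these problem sizes are the
package's own choices for its checks.  Credible intervals are central
quantile intervals; genetic correlations are computed per draw and then
averaged.

## Evolvability statistics

For a unit selection gradient β and mean-scaled **G**:

* evolvability `e(β) = β'Gβ` — expected proportional response along β;
* conditional evolvability `c(β) = (β'G⁻¹β)⁻¹` — response along β when all
  orthogonal directions are held constant by stabilizing selection;
* autonomy `a(β) = c(β)/e(β)`; integration `i(β) = 1 − a(β)`;
* the eigen-summary: mean evolvability trace(G)/k, extremes e_min/e_max,
  and the least/most evolvable directions g_min/g_max (eigenvector signs
  normalized so the dominant component is positive);
* doubling time `t₂ = ln 2 / e` generations, with e a fraction per
  generation.

Conditioning on a named trait subset uses the Schur complement
`G_ff − G_fc G_cc⁻¹ G_cf`; for a single focal trait with all others
conditioning this equals `1/(G⁻¹)_ff`, and the two routes are required to
agree to 1e−12 in the test suite.  Distributions over phenotype space use
gradients drawn uniformly on the unit sphere (normalized Gaussian draws,
seeded); means and medians are both reported for every statistic, because
summaries of nonlinear statistics depend on the order of averaging.
Matrices that are not numerically positive definite are repaired by
flooring eigenvalues at 1e−8 × trace before inversion, with a logged
warning.

A reproducibility caveat established during development: published
posterior summaries of *nonlinear* statistics (mean/median autonomy, mean
conditional evolvability) are averages over MCMC draws of **G** and cannot
be recovered from a printed posterior-mean **G**.  For the canonical
*Dalechampia* matrix, the median autonomy over uniform random gradients of
the printed matrix is ≈0.39 (mean ≈0.44), whereas the corresponding
published posterior summary is 0.533; linear statistics (mean evolvability)
and the eigenvalue extremes agree to printed precision.  The package
reports what it computes.

## Divergence analysis

Among-population (**D**_P) and among-species (**D**_S) covariance matrices
of ln trait means are estimated from the mixed model

    z_ijkl = mu_i + p_ij + b_ijk + q_ijkl

(group, plant-within-group, blossom residual) on ln-transformed phenotypes,
using the same Gibbs machinery with identity structure.  Groups need
strictly positive trait values (zero herkogamy precludes
ln-transformation; such taxa must be excluded) and at least three groups.
On the ln scale, `β'Dβ` is a proportional among-group variance directly
comparable to mean-scaled evolvabilities; no Jacobian correction is applied
between the ln and mean-scaled conventions.  `divergence_along` and
`evolvability_along` share one quadratic-form kernel, so
evolvability–divergence tables are computed with identical projection code.
The species-level model treats populations within species through the
plant-within-group term only.  Models are unweighted.  The deviation metric
pairs each group's `GSD − GAD` (negative values: anthers protrude beyond
stigmas, reducing autonomous selfing) with its mean herkogamy.

## Synthetic data

The generator emulates the statistical structure of the greenhouse design:
10 blocks × 4 parents, all 16 ordered crosses per block including selfs
(160 crosses, 40 half-sib groups), 2 offspring per cross, 2 blossoms per
offspring (640 records), blossoms assigned uniformly at random to 20
measurement dates, and 5% uniform dropout to emulate failed crosses (the
realized data behind the canonical analysis were similarly unbalanced).
Phenotypes are built as `z = mu · (1 + a + b + d + q)` with deviations
drawn from the percent-scaled covariance components, so the mean-scaled
covariance of the simulated data matches the inputs by construction;
breeding values use the matrix-normal construction `chol(A) Z chol(G)'`,
giving Cov(vec a) = **G** ⊗ **A** exactly.

The canonical truth fixture uses the published mean-scaled **G** (diagonal
0.409, 0.801, 6.567%; covariances 0.193, 0.309, −0.591).  Trait means
(5.0, 5.2, 2.8 mm) and the non-genetic components (plant **B** =
diag(0.6, 1.2, 9.0)%, date diag(0.15, 0.15, 0.5)%, residual
diag(0.8, 1.6, 12.0)%) are not published; they were chosen once as
plausible greenhouse values — herkogamy is by far the most variable trait
at every level, and the additive fraction of plant-level variance is kept
moderate so that the design's ability to separate **G** from **B** is
realistic rather than generous.

What the generator does *not* emulate: genuinely related founders (the
original parental plants included known half-sib and grandparental links;
the generator's founders are unrelated unless a multi-generation pedigree
is supplied), non-uniform cross failure, date structure beyond random
assignment, measurement error correlated within dates beyond the date
effect, and any form of selection or drift.  Passing recovery tests
therefore demonstrates calibration of the estimator under the assumed
model, not robustness to field realities.

## Numerical choices and limitations

* Pedigrees are dense; the tabular A recursion and a dense inverse are
  used (designs here are a few hundred individuals).
* Individual ordering is a stable topological sort (generation, then input
  order), making **A** and all seeded analyses bit-reproducible.
* Inverse-Wishart draws use the Bartlett decomposition driven by one numpy
  Generator; identical seeds give identical chains.
* The group-variance model orders groups by first appearance, so fits are
  invariant to renaming groups, and ln-scale fits are exactly invariant to
  global rescaling of the traits.
* The collapsed (G, B) update requires the phenotyped block of **A** to be
  nonsingular (true for any pedigree without duplicate individuals).
* Frequentist coverage of credible intervals at the canonical design size
  is adequate but not exact: the diallel carries limited information about
  the additive/plant split, so interval calibration depends visibly on the
  prior; at 4× the design size the likelihood dominates and posterior
  means land within a fraction of the smallest published evolvability.
* The adaptive-Metropolis component uses diminishing adaptation; runs are
  reproducible given the seed but the kernel is formally non-homogeneous.
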