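# Methods

## The model

`twinpath` implements the classical twin design (CTD) for mixed
continuous/binary phenotypes. Each of *p* analysis variables decomposes
into additive-genetic (A), shared-environment (C) and non-shared-environment
(E) sources through separate lower-triangular Cholesky path matrices
`L_A`, `L_C`, `L_E`. Within a person,

    Sigma_within = L_A L_A' + L_C L_C' + L_E L_E'

and across co-twins

    Sigma_cross(z) = rA(z) * L_A L_A' + L_C L_C'

with the CTD sharing constants fixed: `rA(MZ) = 1`, `rA(DZ) = 0.5`,
`rC = 1` for both zygosities, `rE = 0`. Dominance is not modelled: with
pair data C and D are confounded and cannot be estimated together, so the
ladder is ACE → AE / CE → E.

Binary phenotypes follow the liability-threshold model: the observed
response is the indicator that a latent standard-normal liability exceeds a
threshold τ. A standardized polygenic score (PRS) is declared as a
continuous variable whose variance is entirely additive-genetic (components
`{A}` only); consequently the model-implied MZ cross-twin correlation of a
PRS is exactly 1 and the DZ correlation exactly 0.5.

Standardized variance proportions for variable *i* are
`A_i = (L_A L_A')_ii / v_i` (and likewise C, E), with `v_i` the total
model-implied variance; component correlations are the off-diagonals of
each component covariance scaled to unit diagonal. Correlations for a
variable with no variance in a component are reported as undefined (NaN),
never silently zero.

### Scale identification

A binary variable's liability variance must equal 1 or the threshold scale
is unidentified. The constraint is enforced exactly by reparameterization:
one "carrier" diagonal path per binary variable (E when active, else C,
else A) is not a free parameter but is computed as
`sqrt(1 − sum of the row's other squared paths)`. When an optimizer
excursion pushes the radicand below `1e−6` it is floored there and a
quadratic penalty (weight `1e4`) steers the search back inside; a solution
with active penalty or any parameter at its box bound is flagged
`boundary`.

### Covariates

Covariate ("definition variable") effects enter as per-person liability
mean shifts with thresholds held fixed — algebraically identical to
adjusting the threshold per person. Defaults mirror the analysis the
package reproduces: sex (0 = male, 1 = female) on the diagnosis liability,
age (years, centered at the observed mean by the pipeline) on the
suicide-plan and suicide-attempt liabilities. No interactions, and no sex
adjustment of the item thresholds.

## The likelihood

Each family contributes the likelihood of exactly its observed coordinates
(FIML); missing coordinates are marginalized by deletion, and an
all-missing family contributes zero. Observed continuous values enter
through the exact multivariate-normal density; observed binary values enter
through the rectangle probability of their liability region under the
conditional normal given the continuous observations. Up to 8 binary
coordinates per family are supported (a complete pair with four binary
variables).

Because an A-only PRS implies an MZ cross-twin correlation of exactly 1 and
MZ members carry identical scores, the continuous block of the expected
covariance can be exactly singular. The density is then evaluated on the
supported subspace via the eigendecomposition (pseudo-determinant); null
space residual components are penalized quadratically, which contributes
zero for data consistent with the degeneracy. All models in a comparison
share the same degeneracy structure, so −2LL differences remain valid.

### Rectangle probabilities

`mvn_rectangle_probability` uses the Genz separation-of-variables
transform, which maps the k-dimensional rectangle probability to an
integral over the (k−1)-dimensional unit cube, rather than
inclusion–exclusion over the 2^k CDF corner terms (which cancels
catastrophically for correlated coordinates). Cubature rules are fixed
deterministic point sets, so the likelihood is smooth in the parameters —
important for quasi-Newton optimization with numerical gradients:

| context | k−1 ≤ 3 | k−1 ≥ 4 |
|---|---|---|
| public function (`accurate`) | Gauss–Legendre tensor, 200/48/24 nodes per axis | Sobol, 4096 points |
| dataset likelihood | Gauss–Legendre, 24/10/8 | Sobol, 512 |
| smoke runs (`fast`) | Gauss–Legendre, 12/8/6 | Sobol, 256 |

The public rule meets an absolute accuracy target of 1e−6 for k ≤ 4
(tested against the closed-form orthant value and Monte Carlo). The leaner
likelihood rule carries per-family quadrature error around 1e−5, negligible
against sampling noise at the sample sizes involved. Probabilities are
floored at 1e−300 before taking logs so optimizer excursions cannot produce
an infinite objective.

### Pattern grouping

The conditional covariance of the binary coordinates given the continuous
ones depends only on *which* coordinates are observed, not their values.
Families are therefore grouped by (zygosity, observed-coordinate sets);
each group needs one Cholesky factorization and one batched rectangle
integration, with per-family means, covariate shifts and response patterns
vectorized inside the group. This makes univariate and bivariate fits
nearly independent of sample size.

## Estimation and inference

* **Optimizer**: L-BFGS-B on the packed free-parameter vector with
  numerical gradients (step 1e−6), box bounds (binary-row paths in
  ±0.999, thresholds in ±5, continuous diagonals positive), multi-start
  (default 10 starts; data-informed first start — thresholds from observed
  prevalences, continuous moments from the data, off-diagonals 0.1 —
  then perturbations with SD 0.2, repaired back inside the unit-variance
  budget). The estimator, not any particular optimizer implementation, is
  the target of the re-implementation.
* **Model comparison**: Δ−2LL referred to chi-squared with df equal to the
  free-parameter difference; AIC = −2LL + 2k. The ladder selector fits all
  models (warm-started from the full fit), clamps sub-chi-squared negative
  deltas (≤ 0.5) that are optimizer noise under reduced iteration budgets,
  and among models not significantly worse than the full model (α = 0.05)
  picks the lowest AIC, ties toward fewer parameters. When a variance
  component sits on the boundary the printed chi-squared reference is
  conservative; fits carry a `boundary` flag instead of a chi-bar-squared
  mixture correction.
* **Genetic-submodel nesting**: reduced "CE"/"E" models drop all free A
  entries *except* the own loading of any pure-A (PRS) variable; for the
  trivariate PRS/diagnosis/item model this is exactly a 5-df test
  (a21, a22, a31, a32, a33).
* **Profile CIs**: bisection on the quantity (a path, threshold,
  standardized proportion or component correlation) to the point where the
  profiled −2LL rises by the chi-squared(1) quantile (3.841 at 95%);
  the inner constrained minimization uses SLSQP with an equality
  constraint. Natural bounds (proportions in [0,1], correlations in
  [−1,1]) are respected; hitting one yields a one-sided interval with a
  `boundary` flag.
* **Bootstrap**: non-parametric, resampling whole families with
  replacement within zygosity strata (preserving the twin dependence
  structure — the resampling unit is a design choice, made here at the
  family level), refitting from a warm start, percentile intervals;
  failed replicates are dropped and counted, with a warning above 20%.
* **Threshold homogeneity**: the saturated model frees one threshold per
  twin-order × zygosity cell plus one pairwise liability correlation per
  zygosity (6 parameters); the homogeneous model shares a single threshold
  (3 parameters), giving a 3-df test. Estimated directly by Nelder–Mead on
  the cell-count likelihood.
* **Descriptive correlations**: tetrachoric (binary–binary) and polyserial
  (continuous–binary) estimates use two-step ML — thresholds from the
  margins, correlation from the joint conditional likelihood — which is
  faster than joint one-step estimation and adequate at these sample
  sizes; Pearson with Fisher-z intervals for continuous pairs. Twin-pair
  correlations impose threshold homogeneity (one shared threshold) and use
  singletons through their marginal likelihood. Yates-corrected chi-squared
  floors the corrected deviation at zero (the conservative clamp);
  Cramér's V labels use half-open bins — below 0.1 "negligible",
  [0.1, 0.3) "small", [0.3, 0.5) "medium", ≥ 0.5 "large".

## The synthetic cohort generator

No real cohort ships with the package, so `twinpath.simulate` generates
twin cohorts with the statistical structure the analysis assumes.

**Latent mode** draws per-family factor scores with the CTD sharing built
in: MZ additive scores duplicated, DZ additive scores as
`sqrt(0.5)·common + sqrt(0.5)·unique`, shared-environment scores
duplicated, non-shared scores independent; liabilities are the
Cholesky-weighted sums plus covariate shifts, binary responses are
threshold indicators. **Locus mode** (`simulate_polygenic_pairs`) builds
polygenic scores mechanistically: parents simulated in Hardy–Weinberg
proportions at independent biallelic loci (frequencies uniform on
[0.1, 0.9] by default), children by independent meiosis, scores as
effect-weighted allele-count sums. The expected DZ sibling score
correlation of 0.5 thereby *emerges* rather than being assumed, and the
two routes are tested against each other.

The study-like default (`study_config`) emulates a young-adult twin cohort
of ~1,250 pairs (530 MZ / 720 DZ, 28% singletons, giving roughly 900
complete pairs for the diagnosis), diagnosis prevalence 0.18, a depression
screen of prevalence 0.35 that gates the three suicidal-behavior items
(items are set missing for members not endorsing the screen — which leaves
roughly 150 complete item pairs), ages uniform on 19–39 shared within
pair, sex Bernoulli(0.67 female) shared within MZ pairs only, and 13%
missing polygenic scores. The generating structure is an AE truth with
heritabilities 0.40 (diagnosis), 0.52/0.60/0.80 (ideation/plan/attempt),
1.0 (both PRSs), genetic correlations in the ranges the analysis reports
(high among items, moderate item–diagnosis, ~0.1–0.25 PRS–phenotype), and
weak environmental item–diagnosis correlations. Item thresholds are not
set directly: the unconditional item prevalences are solved (by bisection
on trivariate normal probabilities) so that conditional endorsement among
screened, diagnosed members hits 38% / 14% / 6.5% — a modelling choice,
since only conditional ranges are observable in the emulated design.
Covariate effects are probit-scale: +0.35 female on diagnosis liability,
−0.035 per year of age on plan and attempt.

What the generator does **not** emulate: linkage disequilibrium,
assortative mating, gene–environment correlation or interaction, sibling
(non-twin) family members, measurement error beyond the E component, and
any non-MAR missingness other than the screen gating. Passing tests
therefore show the estimator is correct under the CTD's own assumptions,
not that those assumptions hold in real cohorts.

## Problem sizes used in the test suite

Simulation-based tests choose sizes large enough for their tolerances and
no larger: sharing constants at 20,000–50,000 pairs with 3 Monte-Carlo-SE
bands; estimator bias on a 3 × 2 grid (heritability 0.2/0.5/0.8 ×
prevalence 0.05/0.2) at 2,000 pairs per zygosity, 24 replicates per cell;
profile-interval coverage at 400 pairs per zygosity over 500 replicates;
selection consistency at 500 pairs per zygosity over 100 replicates; the
end-to-end pipeline smoke run on a 200-family cohort with single starts,
30 optimizer iterations and the `fast` cubature profile.

## Known limitations

* No analytic gradients; large multivariate fits rely on finite
  differences and are correspondingly slower.
* No sex-limitation models, no dominance, no families beyond twin pairs.
* Two-step (rather than joint) threshold estimation in the descriptive
  correlations slightly understates threshold uncertainty in their CIs.
* The chi-squared reference for boundary hypotheses (e.g. C = 0) is
  conservative; no chi-bar-squared mixture correction is applied.
* Profile CIs for large multivariate models are expensive (each bisection
  step is a constrained refit); the pipeline computes them only on
  request (`ci_method="profile"`).
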