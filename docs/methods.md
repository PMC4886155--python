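# Methods

## Model

One twin pair is one observation of the (2 + 2K)-vector
(y₁, y₂, x₁, x₂): two phenotypes and two K-vectors of covariates, in that
fixed coordinate order.  The model is a single multivariate normal per
zygosity group:

* **Phenotypic residual covariance (ACE).**  After removing the covariate
  effects, phenotypic variance is σ²_A + σ²_C + σ²_E and the cross-twin
  covariance is ρσ²_A + σ²_C with ρ = 1 (MZ) / ½ (DZ).  σ²_A and σ²_C are
  constrained non-negative; σ²_E strictly positive (the model is degenerate
  without an individual-level residual).
* **Covariate covariance.**  A twin's own covariate covariance is
  Σ_w + Σ_b; the cross-twin block is Σ_b.  Σ_b captures everything co-twins
  share (family environment and, for DZ pairs, partially shared genetics);
  Σ_w the rest.  Σ_w must be positive definite, Σ_b positive semi-definite.
  By default MZ and DZ pairs share one (Σ_w, Σ_b); `JointModel.cov_dz`
  allows a DZ-specific structure at the evaluation level (the estimators do
  not free it — deliberately out of scope).
* **Coupling.**  Covariates act linearly on the phenotypic mean
  (μ_y + x'β).  The implied joint covariance has phenotypic variance
  ACE-total + β'(Σ_w+Σ_b)β and cross-twin phenotype covariance
  ρσ²_A + σ²_C + β'Σ_b β.  The joint mean is
  (μ_y + β'μ_x, μ_y + β'μ_x, μ_x, μ_x) — the unique choice consistent with
  the conditional model.  Conditioning the joint normal on the covariates
  recovers the conditional model exactly (Schur complement); this identity
  is enforced at machine precision in the tests.

## Likelihood evaluation

**Full information.**  A pair with missing entries contributes the MVN
log-density of exactly its observed coordinates (marginalization =
coordinate selection).  Missing phenotypes are allowed and marginalized
like any coordinate; records with no observed entry at all are rejected at
load time.  For speed, pairs are grouped by (zygosity, missingness
pattern); each group enters through its count, sum vector and raw
second-moment matrix, precomputed once.  A likelihood evaluation then
performs one small batched Cholesky factorization per pattern block and is
independent of the number of pairs.  The gradient with respect to the
joint mean and covariances is accumulated analytically per pattern and
chained to the working parameterization through a complex-step derivative
(step 1e-20) of the cheap moment builder, i.e. exact to machine precision.

**Usual approach.**  `twinwise_delete` removes any individual with a
missing covariate or missing phenotype (phenotype and covariates together);
a complete co-twin survives as a singleton; pairs losing both twins are
dropped.  The likelihood is the product of bivariate-normal pair terms
(shared μ_y across pairs and singletons, standard SEM practice) and
univariate singleton terms with variance σ²_A + σ²_C + σ²_E.

**Validity region.**  A covariance whose smallest eigenvalue is below
1e-10 × its largest is treated as an invalid parameter point: the
likelihood reports −∞ and the optimizer backtracks, rather than crashing
in a factorization.

## Estimation

* **Parameterization.**  Variance components on the log scale; Σ_w and Σ_b
  through lower-triangular Cholesky factors with log-scale diagonals
  (optionally an exchangeable variance/correlation pair per matrix via
  `covariate_structure="exchangeable"`, with the correlation mapped to
  (−1/(K−1), 1) through a scaled logistic).  This makes the search
  unconstrained and smooth; a component estimate below 1e-6 is flagged as a
  boundary solution.  The Cholesky route constrains Σ_b to be (numerically)
  positive definite during optimization; a truly singular Σ_b surfaces as a
  boundary estimate rather than an interior one.
* **Starting values.**  (0.4, 0.2, 0.4) × the sample phenotypic variance
  for (A, C, E); β and μ_y from OLS on complete-case individuals; μ_x from
  observed covariate means; Σ_b from the symmetrized cross-twin covariate
  covariance of complete pairs and Σ_w from the within-twin covariance
  minus Σ_b, both eigenvalue-floored to be safely positive definite.
* **Optimizer.**  L-BFGS-B with analytic gradients, at most 2000
  iterations.  The gradient max-norm criterion (1e-5) is made binding by
  setting the relative-objective tolerance well below the 1e-8 level, so
  reported maxima are gradient-converged; non-convergence is flagged on the
  result, never silent.
* **Standard errors.**  Observed information in the *natural*
  parameterization (variances, β, μ, covariance entries), obtained by
  central finite differences of the analytic score (full-information) or of
  the log-likelihood (usual approach); SEs are square roots of the inverse
  information's diagonal, NaN with a flag when the information is not
  invertible (e.g. on a boundary).  The h² SE uses the delta method on
  σ²_A/(σ²_A+σ²_C+σ²_E) with the ACE covariance block.

## Simulator

`simulate_dataset` draws covariates from the 2K-dimensional normal implied
by (Σ_w, Σ_b) and phenotypes conditionally with the zygosity-specific ACE
covariance.  Defaults are the study design this package is organized
around: 280 MZ + 720 DZ pairs (the typical European twin-register ratio),
ACE = (0.5, 0.3, 0.2), μ_y = 0, μ_x = 0, exchangeable covariate structure
(variances 1, within correlation .1, between correlation .5), and equal
regression weights solved so the covariates explain 39% of the total
phenotypic variance — closed form
β = √(f/(1−f) · σ²_P / 1'(Σ_w+Σ_b)1), giving a total variance of
σ²_P/(1−f) ≈ 1.64 at f = 0.39.

`impose_missingness` deletes **exactly** round(p · 2nK) covariate entries
(round-half-to-even, for cross-platform determinism).  Entry weights:
uniform (MCAR); a logistic in the twin's phenotype,
1/(1 + exp(2 + 1.7·y)), so deletion probability rises as the phenotype
falls (MAR); the same logistic in the covariate's own value (MNAR — the
covariate scale matches the phenotype scale here, so the same intercept
and slope are sensible).  Selection is weighted sampling *without*
replacement of the exact count — equivalent to sequential
probability-proportional-to-remaining-weight draws — implemented by
ranking Exp(1)/weight keys.  Phenotypes are never masked by these
mechanisms; that matches the scenario being studied (covariate
missingness), and the full-information likelihood handles missing
phenotypes anyway if a dataset contains them.

**What the simulator does not emulate:** categorical covariates and
liability thresholds (real covariates are often categorical; the dummy
coding and standardization helpers prepare such data, but the generator is
Gaussian), zygosity-dependent covariate structure or missingness,
selective sampling of families, and measurement error in zygosity.
Passing Monte-Carlo tests therefore demonstrates correctness of the
estimators under the stated Gaussian design, not robustness to these
real-data features.

## Study harness

`run_study` executes condition × replicate × estimator, with per-replicate
RNGs spawned as `SeedSequence(master_seed, spawn_key=(condition, rep))` —
execution order and parallel scheduling cannot change the data.  Failed or
non-converged fits are recorded, excluded from aggregation, and a cell
with more than 5% failures is flagged unreliable.  Aggregates report both
the empirical SD of estimates across replicates and (when enabled) the
mean model-based SE; precision comparisons between estimators read the
same either way, and the empirical-SD reading is the default because it
needs no per-replicate information matrix.  The desk-scale default is 200
replicates per cell — Monte-Carlo SEs (SD/√200) are carried through the
aggregate table so that recovery checks can be stated in MC-SE units; the
original-scale 1000 replicates is a parameter away.

## Known limitations

* The estimators assume joint normality of phenotype and covariates;
  categorical covariates enter only through dummy coding, which bends the
  normality assumption (workable in practice, unmodelled here).
* Under MNAR deletion the full-information estimator is not consistent;
  at the 10% level the design's unique-environment component drifts to
  ≈ 0.21 (reproduced by the acceptance checks). Larger MNAR rates would
  bias it further.
* Single documented start; no global search.  With the moment-based starts
  non-convergence is rare in the studied designs, but multimodal surfaces
  (tiny n, boundary components) may need user-supplied restarts.
* No ADE, sex-limitation, GxE moderation, or multivariate phenotypes.
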