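# Methods

## Model family and moment algebra

All models are specified as structural matrices whose cells are either fixed
constants or free-parameter labels (shared labels impose equality).  For each
latent kind *k* ∈ {A, C, E} the within-twin observed-scale covariance is a sum
of component contributions:

* simplex: `Σ = (I − B)⁻¹ diag(i²) (I − B)⁻ᵀ` with B strictly
  sub-diagonal (first-order), innovation variances fixed to 1 and the scale
  carried by the innovation path coefficients `i_t`; latent→observed loadings
  fixed to 1;
* factor: `Λ diag(s²) Λᵀ` (orthogonal factors with path scales);
* free covariance: the latent covariance entered directly on the variance
  scale (correlated-factors reference, growth-factor covariance, univariate
  A/C/E variances);
* diagonal: `diag(d_t²)` occasion-specific inputs (per-kind residuals);
* dual change: `L(β) Φ L(β)ᵀ` with `L(β)` the level/constant-change loadings
  of the latent-difference recursion `η_t = (1+β) η_{t−1} + s`.

Twin-pair moments stack two phenotype vectors; the cross-twin block of kind
*k* is `r_k × Σ_k` with the classical fixed correlations r_A = 1.0 (MZ) / 0.5
(DZ), r_C = 1.0, r_E = 0; the transient residual ε is uncorrelated across
twins.  Means are `design @ coefs` (occasion means, or growth-factor means
through the growth loadings) plus a sex regression applied per twin (a
definition variable).  The same component objects generate data: every
component draws its latent standard normals with the kind's cross-twin
correlation, so simulated moments converge to the implied moments by
construction — that generative/analytic agreement is tested for every family.

## Identification conventions

* Autoregression: one transmission coefficient per kind equated across time;
  innovation variances fixed to 1; the occasion residual equated across
  occasions.  Transmission coefficients are box-bounded to (−0.99, 0.99):
  the model's substantive interpretation is variance accumulating toward a
  stable asymptote, and unbounded fits occasionally wander to explosive
  (|β| > 1) representations of a weakly identified shared-environment chain.
* Latent growth: intercept/linear/quadratic loadings (1, t, t²) at t = 0…5;
  free factor covariance and free occasion residual paths per kind;
  growth-factor means free.
* Dual change: per kind, a level/constant-change factor pair with free 2×2
  covariance and one proportional coefficient (bounded as above); the mean
  structure is a linear trajectory, so the β = 0 limit reproduces the linear
  growth model exactly (tested).
* Common pathway: each latent liability's first loading is fixed to 1 and its
  A/C/E path scales are free — an identification equivalent to the
  unit-variance-factor convention with the same free-parameter count, chosen
  because it keeps every cell a plain label and needs no nonlinear
  constraint.  With k ≥ 2 factors the loadings are echelon (factor j fixed
  to 0 before occasion j and 1 at occasion j) and the factors orthogonal;
  correlated ACE-decomposed factors are not identified without additional
  constraints that are not publicly specified for this design.
* Univariate A/C/E: variance-scale parameters, unbounded below, so the shared
  component may go negative — its sign indicating whether shared environment
  (positive) or genetic non-additivity (negative) predominates.  Shared
  environment and genetic dominance are negatively confounded in twins reared
  together and are not modelled simultaneously.
* Saturated model: free means and covariance cells per twin order and
  zygosity; homogeneity tests equate means, then variances, across twin
  order and zygosity by label sharing.

## Estimation

Raw-data FIML: each pair contributes the Gaussian −2 log-likelihood of its
observed subvector.  Pairs are grouped by (zygosity, observation pattern);
per group the sufficient statistics (∑y, ∑yyᵀ and the sex cross-moments) are
precomputed once, so an objective evaluation costs a few batched small-matrix
operations per distinct pattern, independent of sample size.  The grouped
evaluation is contract-tested against the naive per-pair loop.

The gradient with respect to the implied moments is exact; it is chained to
the free parameters through a central-difference Jacobian of the (cheap)
moment-assembly map.  Optimization is L-BFGS-B on per-parameter scaled
coordinates (scales from the moment-Jacobian column norms, which tames the
extreme leverage of quadratic-growth variances), with seeded jittered
restarts and a final Hessian-restart polish; convergence is declared on
optimizer success, small gradient norm, or stationarity of the polish run.
Outside the positive-definite cone (reachable under variance-scale
parameterizations) the objective is a smooth eigenvalue penalty whose
gradient points back toward the cone.

Standard errors come from the inverse observed information (symmetrized
central differences of the gradient, relative step 1e−4); non-positive
curvature (typical at boundary estimates) yields flagged NaNs rather than an
error.  Profile confidence intervals re-optimize all other parameters on a
bracketed bisection of the −2LL level set (χ²₁ 0.95 quantile 3.841 by
default); a bound that cannot be bracketed is reported one-sided.

## Model comparison and pruning

Nested models are compared by Δ−2LL with df equal to the free-label
difference; the label-subset nesting check can be overridden where nesting is
structural rather than label-wise (every theoretical family vs the
correlated-factors reference).  Variance-type parameters tested at their
boundary have non-standard null distributions; the naive χ² p-value is
reported with a caveat flag, matching the framework reproduced here.  AIC is
−2LL + 2·ep, used for ranking only (ties broken by fewer parameters, then
name); non-converged fits stay in the table but are excluded from selection.

The pruning workflow tests each shared-environment innovation beyond a
configured earliest-kept occasion with the profile-interval-spans-zero rule.
For a path coefficient this is exactly equivalent to the likelihood-ratio
test of fixing the path to zero (the profile interval contains zero iff that
Δ−2LL is below 3.841), so the decision uses one warm-started constrained
refit per innovation rather than a two-sided bound search.  When the
surviving occasions form a leading block, the model is rebuilt with the
trailing transmissions removed (the post-hoc topology).  Note that this
truncated model is *not* nested in the equated-transmission full model — the
shared β would still carry the last retained occasion's variance forward —
so the post-hoc row in the comparison table is an AIC comparison; its Δ−2LL
is reported descriptively and can be slightly negative.

If a nested fit ever beats its reference (under-convergence), the workflow
refits the reference warm-started from the nested solution, which is a
feasible point of the reference's space and therefore restores the nesting
inequality up to optimizer tolerance.

## The synthetic cohort

The generator stands in for a restricted-access accelerated longitudinal twin
cohort.  What it emulates: two 6-item three-point ordinal domains summed to
0–12 and square-root transformed; six 4-year age intervals from 12 to 35; MZ
pairs same-sex, DZ sexes independent, a sex effect on means (default −0.14 on
the transformed scale); and the cohort's missingness profile — the number of
observed intervals per subject drawn with probabilities proportional to
1639 : 972 : 931 : 229 for 1–4 intervals (no subject observed at more than
four, none removed entirely), over a contiguous window with a uniformly drawn
start.  What it does not emulate: item-level dependence beyond a single
common factor per domain, age heaping and irregular within-wave age spread
beyond a configurable jitter, attrition correlated with the phenotype, and
any real-cohort joint distribution.  Passing tests therefore validate the
estimator and workflow under the assumed statistical structure, not the
substantive findings of any real cohort.

Two canonical truths are shipped:

* `default_truth` — the study-structure configuration: a persistent genetic
  simplex (β_a = 0.75, innovations 0.45…0.25), shared-environment innovations
  at the first two occasions only (0.30, 0.15) with the later innovation
  paths structurally zero and a weak shared-environment transmission
  (β_c = 0.30, reflecting a reported non-significant C transmission and
  shared-environment influence confined to adolescence), weakly persistent
  non-shared environment (β_e = 0.40, innovations 0.20), dominant transient
  residual (0.50), means declining from 1.50 to 1.30 on the transformed
  scale.  Because the zero innovations are free labels of the fitted full
  model, the generating model is nested in it — the standard design for a
  pruning study.
* `interior_truth` — every parameter bounded away from zero and from
  identifiability ridges (E innovations 0.35, β_e = 0.50): an E process whose
  innovations nearly vanish trades off against the transient residual along a
  likelihood ridge that no estimator can resolve at realistic n, so recovery
  and calibration studies use this configuration.  Recovery studies run on
  complete records: they validate the estimator itself, while the
  missing-data path is exercised by the likelihood oracle and by the
  model-recovery and pruning studies, which run under the full cohort
  missingness.

Ordinal emission maps standardized latent scores to items through
item-specific noise (SD 0.8) and thresholds (0.9, 2.0) chosen so roughly 70%
of responses fall in category 0, giving the right-skewed domain sums typical
of distress screeners.  Continuous emission writes the transformed score
directly for exact pipeline-closure tests.

## Data preparation conventions

Domain scores are missing if any constituent item is missing (no prorating —
conservative on a 6-item sum).  Age bins are half-open 4-year intervals
[12, 16) … [32, 36), so every age maps uniquely; ages of 36 and over are
excluded (the sparse oldest interval), ages under 12 excluded unless within a
configurable tolerance.  Six occasions are used throughout: the growth
loadings 0…5 and the six latent components per kind presuppose six intervals
in 12–35.  When two assessments of one subject land in the same interval the
one closest to the bin midpoint is kept and the discard logged.  Singleton
twins are retained with an all-missing co-twin (FIML uses them); families
with more than two subjects or conflicting zygosity are structural errors.

## Statistical test design

Simulation-based checks fix their seeds and state their conditions:

* Moment oracles compare empirical and implied covariances elementwise within
  4 Monte-Carlo standard errors at 10⁵ pairs per family.
* Parameter recovery enforces the per-parameter "|bias| < 2 MC SE" rule
  familywise: with ~30 parameters checked simultaneously, the per-parameter
  rule is applied at a Bonferroni-adjusted bound (≈3.2 SEs at 29 parameters;
  reduces to ≈2 for a single parameter), which controls the probability of a
  false alarm across the whole parameter vector at the same 5% level the
  2-SE rule implies for one parameter.  Innovation paths are compared in
  absolute value (their sign is not identified).
* Model-family recovery and pruning success are binomial rates over seeded
  replicates at n = 2000 pairs per zygosity under the cohort missingness;
  problem sizes and replicate counts (10–25) were chosen for single-CPU runs.
* The pruning success rate is structurally limited: the post-hoc truncation
  discards the small shared-environment variance that the retained
  transmission genuinely carries past the last kept occasion (≈1.3 units of
  −2LL at n = 4000 pairs under `default_truth`), and the joint cost of
  zeroing four boundary parameters has a heavy right tail, so the expected
  success rate sits near 80% rather than near 100%.

## Known limitations

* No dominance (ADE) models, no sex-limitation models, no gene–environment
  interaction or rater-bias structure.
* Boundary likelihood-ratio p-values use the naive χ² reference (flagged),
  not mixture nulls.
* The common-pathway implementation with k ≥ 2 uses orthogonal echelon
  factors; fits are rotation-fixed, so individual loadings should be
  interpreted up to that convention.
* Profile intervals assume a unimodal profile; for sign-symmetric path
  coefficients they are reported on the positive branch.
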