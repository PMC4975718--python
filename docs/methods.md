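# Methods

This note records the models, the synthetic-data generator, the numerical
choices and the known limitations of `streamnet`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stream networks

A network is a rooted tree of segments directed toward a single outlet;
every non-terminal segment has exactly two upstream children (dendritic
branching, no braided or diverging channels). Locations are addressed by
`(segment, updist)` with `updist` the along-stream distance from the
outlet. Two locations are *flow-connected* when one lies downstream of the
other; the along-stream distance between flow-unconnected locations runs
through their common junction and is provided for completeness, but the
tail-up covariance assigns such pairs exactly zero.

The generator grows a tree by repeatedly splitting a uniformly chosen
terminal segment into two children until the requested count is reached,
so a network with `k` confluences has `2k + 1` segments and even counts
are rejected; the study's nominal sizes 100 and 2000 are realized as 101
and 2001 segments. Segment lengths are iid exponential (mean 1 network
unit by default). Flow values count the headwater segments upstream of
each segment — the simplest additive choice, so mass balance
`f_c = f_a + f_b` holds exactly at every confluence and confluence weights
`ω_k = f_k/f_c` sum to one. The planar embedding splits branch directions
±35° around the parent direction with true segment lengths; it exists only
to supply Cartesian coordinates for the Euclidean component and makes no
crossing-free guarantee.

Confluence-weight products use the plain product `π = Πω_k` of flow
ratios; the square-root convention that keeps the tail-up marginal
variance exactly stationary is available as a switch
(`use_sqrt_weights`) but is not the study's convention.

## Generating model

All data are Gaussian. With covariates `X1, X2, X3` and spatial fields
`Z1` (tail-up) and `Z2` (Euclidean):

```
Y(s) = β₀ + k₁(β₁X₁ + β₂X₂ + β₃X₃) + Z₁(s) + k₂ Z₂(s) + ε,   ε ~ N(0, σ²I)
```

with fixed constants `β₀ = β₁ = β₂ = 1`, `β₃ = 0`, `σ² = 0.1`; `Z1` has
partial sill 1 and range `r_Φ`; `Z2` (present iff `k₂ = 1`) has sill 1 and
range `0.3v`. The covariates are independent tail-up fields with partial
sill 1, range `v/2` and nugget 0.1. `X2` is an unobserved spatially
structured confounder (never given to the fitted models); `X3` is
observed but irrelevant. The design crosses five two-level factors —
`k₁ ∈ {0.1, 1}`, `k₂ ∈ {0, 1}`, `r_Φ ∈ {0.3v, v}`, `n ∈ {100, 500}`,
`n_seg ∈ {100, 2000}` — into 32 scenarios.

`v` is the maximum pairwise stream distance over the union of both
observation sets and the 1000 prediction locations, computed once per
network and frozen, so all ranges are expressed relative to network
extent. Networks and point locations are built once per study run and held
fixed across scenarios and replicates; covariate fields are redrawn each
replicate (a `redraw_covariates` flag restores scenario-fixed fields), so
confidence-interval coverage reflects design variability as well as noise.
Observation and prediction values come from one joint multivariate-normal
draw so that prediction scoring sees the same latent surfaces. Replicates
are seeded through `SeedSequence(base_seed, spawn_key=(scenario, rep))`
and are bit-reproducible.

Simulation uses dense Cholesky factors with a 1e-10 diagonal jitter
escalated ×100 on failure; factors are cached per scenario since they
depend only on the frozen geometry and the scenario's ranges.

## Tail-up geostatistical fit

The REML criterion is `log|Σ| + log|XᵀΣ⁻¹X| + yᵀPy` (−2 × restricted
log-likelihood up to a constant), with `Σ = θ_v R_tu(r_Φ) + σ²_ng I`
(+ `θ_e R_eu(r_Ψ)` when the Euclidean component is modelled). The overall
scale is profiled out analytically, so the quasi-Newton (L-BFGS-B) search
runs over the variance *proportions* (log-ratio parameterization, bounded
±12) and log ranges (bounded around the observed distance scale). Three
starts are used: 80/20, 50/50 and 20/80 sill/nugget splits with ranges at
the median and maximum pairwise stream distance. The profiled optimum
coincides with the full REML optimum; `reml_neg_loglik` evaluates the full
criterion at any parameter vector. Non-convergence from every start is
flagged (`converged=False`) and the best candidate returned.

Fixed effects are GLS at the estimated covariance with
`Cov(β̂) = (XᵀΣ̂⁻¹X)⁻¹`; 90% intervals use the normal quantile 1.645
(no t-correction — the simulation sample sizes make the difference
negligible). Universal kriging predicts a *new observation*: the variance
includes the nugget (held-out responses contain ε) and the fixed-effect
extrapolation term `mᵀ(XᵀΣ̂⁻¹X)⁻¹m`. Parameter uncertainty in θ̂ is
ignored (plug-in kriging), the standard practice.

## Penalized network-spline fit

The design is `C = [B | X1 | X3 (| surface basis)]` with no intercept
column — the segment term absorbs it, and the intercept is not reported.
The roughness penalty has two rows per confluence with entries
`±f_a/f_c` and `±f_b/f_c`, so `βᵀDᵀDβ` equals the flow-weighted sum of
squared segment differences; its null space (constant vectors) is handled
by a 1e-8 ridge on the segment block. For a candidate `λ` the penalized
normal equations are solved by dense Cholesky; `df` is the trace of the
hat matrix computed as `tr(C M⁻¹Cᵀ)` via `n` solves, and
`σ̂² = RSS/(n − df)`.

Smoothing is selected over a 50-point log-spaced grid `1e-4…1e6`
(crossed with a 10-point grid for the surface smooth when present), ties
broken toward heavier smoothing, minimizing the corrected AIC
`AICC = log(σ̂²) + (2df + 2)/(n − df − 2)` — the Hurvich–Simonoff–Tsai
criterion with the error variance inside the logarithm. The `aicc`
helper implements the formula for whatever scale estimate it is given;
selection passes the variance. Applying the criterion to `σ̂` instead
doubles the relative complexity penalty and over-smooths markedly
(median df 4 instead of 31 at n=100 in the sparse scenario), driving the
spline toward the linear baseline; the variance-scale criterion is the
one consistent with the criterion's source and is used throughout.

Coefficient and prediction uncertainty use the ridge-posterior
covariance `σ̂²(CᵀC + P_λ)⁻¹` — the standard penalized-spline (Bayesian)
convention, which accounts for smoothing bias that a frequentist sandwich
form ignores; at `λ = 0` both coincide with the OLS covariance.
Prediction intervals add `σ̂²` for the new observation. Fixed-effect
undercoverage at small network sizes is a genuine property of the model
(the penalty shrinks the segment field, leaving spatially correlated
residual structure partly unaccounted), and is the behaviour the study
measures — no small-sample correction is applied.

The optional planar surface uses cubic B-spline marginal bases (15 basis
functions per axis by default, capped for tractability) on equally spaced
knots over the *network bounding box* — not the data range — so
prediction locations always lie inside the basis support; the penalty
sums second-order difference penalties over each margin. The surface is a
nuisance adjustment for Euclidean structure, not an object of inference.

## Study driver and metrics

Each replicate fits the tail-up model, the network spline and OLS to the
same data (Euclidean/surface terms included exactly when the scenario has
`k₂ = 1`). Per-replicate scores: RMSPE, mean prediction bias and 90%
prediction-interval coverage over the 1000 held-out locations; RMSE, bias
and 90% confidence-interval coverage averaged over the `X1` and `X3`
coefficients, with the `X1` truth equal to `k₁β₁` (the fitted coefficient
estimates the composite effect). Scenario summaries are means over
replicates with Monte-Carlo standard errors `√(p(1−p)/reps)` attached to
coverages. Replicates where any fit fails are dropped for all models
(keeping comparisons paired) and counted. Timing records median and
5%/95% quantiles of wall-clock fit time; only growth trends are
meaningful.

## Problem sizes

The validation experiments in `tests/test_acceptance.py` and
`scripts/acceptance.py` use 200 replicates of the small-network scenarios
(the package's chosen Monte-Carlo size for desk-scale validation; the full
study default is 500, available through the CLI), with three-Monte-Carlo-
standard-error tolerances where a point value is claimed. The large
network (nominal 2000 segments) is exercised through the CLI and unit
tests rather than the replicated experiments; its spline fits use the
same dense solvers and are the slow cells of the full grid.

## What the generator does and does not emulate

It reproduces the features the models are sensitive to: dendritic
topology with mass-balanced flows, flow-connected-only tail-up
covariance, spatially structured covariates, an unobserved confounder
and Euclidean leakage across branches. It does not emulate real GIS
geometry (planarity, sinuosity, catchment shape), non-Gaussian responses,
preferential sampling, temporal structure, or tail-down dependence
(spatial correlation between flow-unconnected locations through the
network itself). Passing tests therefore validate the estimators under
the stated Gaussian tail-up world, not the full range of field data.

## Known limitations

* Dense linear algebra throughout: fits are comfortable to a few thousand
  segments / a few thousand observations but are not engineered for
  larger problems.
* REML uses plug-in kriging variances; coverage statements are about the
  simulation's scenarios, not small-`n` guarantees.
* The embedding may self-intersect; only pairwise Euclidean distances are
  consumed downstream.
* The `.ssn` interchange format and generalized (non-Gaussian) responses
  are out of scope.
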