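# streamnet

Spatial statistical models for data observed on dendritic (branching)
stream networks, and a replicated simulation study that validates and
compares them.

Stream-network data — pollutant concentrations, temperature, biodiversity
counts — carry spatial structure that ordinary geostatistics mishandles:
flow direction matters, covariance should respect confluences and flow
volumes, and plain stream distance inside a standard kernel does not give a
valid covariance. `streamnet` implements the two main remedies:

* **Tail-up geostatistical model** (`TailUpGLS`). A Gaussian linear model
  `y = Xβ + Z₁ (+ Z₂) + ε` where `Z₁` has the exponential *tail-up*
  covariance

  `C(r, s) = π_rs · θ_v · exp(−h/r_Φ)` for flow-connected pairs, `0`
  otherwise,

  with `h` the along-stream (hydrologic) distance and `π_rs` the product of
  confluence flow-weights `ω_k = f_k / f_c` between the pair. An optional
  `Z₂` adds an exponential Euclidean component for structure that leaks
  across unconnected branches. Variance parameters are estimated by REML;
  fixed effects by GLS; prediction by universal kriging with intervals that
  target new observations.

* **Flow-weighted penalized network spline** (`NetworkSplineModel`). One
  mean parameter per stream segment, selected by an incidence matrix `B`,
  with a mass-balance roughness penalty `λ βᵀDᵀDβ` whose rows weight
  segment differences at each confluence by `f_a/f_c`, `f_b/f_c`.
  Covariates enter unpenalized; an optional tensor-product B-spline surface
  handles Euclidean structure. The smoothing parameter minimizes a
  corrected AIC; uncertainty uses the ridge-posterior covariance
  `σ̂²(CᵀC + P_λ)⁻¹`.

A non-spatial OLS baseline, a seeded synthetic-data generator (random
dendritic networks with mass-balanced flows, tail-up covariate fields, an
unobserved spatial confounder) and a scenario study driver complete the
package.

## Worked example

```python
from streamnet import (StudyGeometry, ScenarioConfig, ScenarioSimulator,
                       fit_vhpt, krige_predict, select_lambda, od_predict)

geometry = StudyGeometry.build(n_seg=100, seed=1)   # network + fixed points
cfg = ScenarioConfig(k1=1.0, k2=0, r_phi_factor=0.3, n=100, n_seg=100)
dataset = ScenarioSimulator(geometry, cfg, base_seed=1).replicate(0)

fit = fit_vhpt(dataset)          # REML fit of the tail-up model
print(fit.summary())
```

prints

```
Tail-up geostatistical model (REML)
  observations: 100   fixed effects: 3   converged: True
  -2 restricted loglik (+const): 124.5849
  variance parameters:
     tu_partial_sill: 2.13602
            tu_range: 8.42863
              nugget: 0.280716
          term       coef        se      lo90      hi90
     intercept     1.2353    0.2664    0.7971    1.6735
            X1     1.1672    0.1769    0.8763    1.4582
            X3    -0.1371    0.1486   -0.3815    0.1073
```

The true `X1` coefficient is 1 (and 0 for the irrelevant `X3`); the fitted
partial sill absorbs both the tail-up field and an unobserved spatially
structured confounder, and the nugget absorbs the iid noise (0.1) plus the
confounder's micro-scale variance. Kriging and the spline fit follow the
same pattern:

```python
pred = krige_predict(fit, dataset)        # universal kriging + 90% PIs
spline = select_lambda(dataset)           # AICC-selected smoothing
spred = od_predict(spline, dataset=dataset)
```

## Command line

```bash
streamnet network --nseg 101 --seed 1 --out net.json   # generate a network
streamnet simulate --scenario 0 --reps 3 --out sim     # emit datasets
streamnet run --scenarios "k2=0;n=100" --reps 100 --seed 1 --out metrics.csv
streamnet timing --n 50,100,200 --nseg 51,201 --out timing.csv
```

`run` executes cells of the 32-scenario factorial design (fixed-effect
strength × Euclidean presence × spatial range × sample size × network
size) and writes per-scenario, per-model RMSPE, bias and 90% interval
coverages with Monte-Carlo standard errors.

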