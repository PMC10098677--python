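# pcamiss — PCA for data with heterogeneously missing entries

`pcamiss` estimates the leading principal subspace of high-dimensional data in
which entries are missing — possibly with very different rates across rows and
columns, and possibly not at random. It targets the settings practitioners
actually face: recommendation matrices where popular items are rated far more
often, meta-analyses where covariates appear in only some studies, and
longitudinal measurements truncated by a stopping event.

## The model and the method

The data model is a K-spiked factor structure

```
Y = U V_K' + Z,          y_i = V_K u_i + z_i,
```

with `V_K ∈ R^{d×K}` an orthonormal loading matrix, factor scores
`u_i ~ N(0, Σ_u)` and isotropic noise `z_i`. We observe the pair
`(Y ∘ Ω, Ω)` where `Ω` is a binary revelation matrix, and want `Col(V_K)`,
the leading eigenspace of `Σ_y = V_K Σ_u V_K' + σ² I`. Errors are measured
by the Davis–Kahan sin-theta loss
`L(V̂, V) = 2^{-1/2} ‖V̂V̂' − VV'‖_F ∈ [0, √K]`.

Two estimator families are provided:

* **Weighted-covariance spectral estimators.** The zero-filled second-moment
  matrix is reweighted entrywise to undo observation attenuation: with a
  single observed fraction `p̂` (the OPW estimator,
  `Ĝ = (n^{-1} Y_Ω' Y_Ω) ∘ Ŵ`, `Ŵ = p̂^{-2}{11' − (1 − p̂)I}`), with
  per-pair co-observation counts (`W̃_jk = n / Σ_i ω_ij ω_ik`, robust to
  column heterogeneity), or per group of a fully observed categorical
  covariate (the grouped OPWv variant). Their top-K eigenvectors are
  consistent initialisers.
* **Iterative refinement.** Starting from any such initial estimate, each
  iteration (i) *screens* rows, keeping row `i` only if it has more than `K`
  observed entries and `σ_K(V_{J_i}) ≥ √(|J_i|/d)/σ*`; (ii) *imputes* each
  kept row by least-squares projection of its observed entries onto the
  current loadings, keeping observed entries verbatim; and (iii) updates the
  loadings to the top-K right singular space of the imputed matrix. In the
  noiseless case this contracts the error geometrically; with noise it is
  markedly more accurate than nuclear-norm matrix completion tuned by an
  oracle.

Baselines for benchmarking — mean imputation, softImpute-style nuclear-norm
imputation (with per-instance oracle λ), hardImpute, and an EM algorithm for
a multivariate normal with missing data — are included, along with synthetic
generators for MCAR (homogeneous and heterogeneous grids), MAR (missingness
driven by an observed category) and MNAR (Bernoulli-thinned Gaussian random
walks observed until a threshold exit) mechanisms.

## Worked example

```python
import numpy as np
from pcamiss import (
    AlgoConfig, ObservedData, MissingnessConfig, SpikedModelConfig,
    fit_primepca, generate_mask, generate_spiked, hetero_covariance,
    init_estimator, make_vk_twospike, sin_theta_loss,
)

vk = make_vk_twospike(500)                      # fixed two-spike loadings
model = SpikedModelConfig(n=2000, d=500, K=2, sigma_u=3600 * np.eye(2),
                          loadings=vk, noise_sd=1.0, seed=0)
y = generate_spiked(model)                      # complete data, SNR = 14.4
mask = generate_mask(2000, 500, MissingnessConfig("H1", {}, seed=1))
data = ObservedData.from_full(y, mask)          # ~5% of entries observed

v0 = init_estimator(hetero_covariance(data), 2) # spectral initialiser
fit = fit_primepca(data, v0, AlgoConfig(K=2))
print(f"initialiser loss: {sin_theta_loss(v0, vk):.3f}")
print(f"refined loss:     {sin_theta_loss(fit.final, vk):.3f}  "
      f"({fit.iterations_run} iterations, converged={fit.converged})")
```

```
initialiser loss: 0.262
refined loss:     0.056  (287 iterations, converged=True)
```

Despite seeing only one entry in twenty, the refined estimate is within
sin-theta distance 0.056 of the true two-dimensional subspace (the loss of a
random guess would be near √2 ≈ 1.41); the spectral initialiser alone stops
at 0.26.

A command-line interface mirrors the library: `pcamiss fit` estimates
loadings/scores from an NA-coded or MatrixMarket file, `pcamiss simulate`
writes synthetic datasets, and `pcamiss bench` runs replicated benchmark
scenarios from presets or a YAML config.

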