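# Methods

## Model and estimands

The package assumes the spiked factor model `Y = U V_K' + Z` with `n`
independent rows: `V_K ∈ R^{d×K}` has orthonormal columns, the factor scores
`u_i` are i.i.d. `N(0, Σ_u)` and the noise entries are i.i.d. `N(0, σ²)`
(`σ = 0` gives an exactly rank-K matrix). The estimand is the column span
`Col(V_K)`, equivalently the leading K-dimensional eigenspace of
`Σ_y = V_K Σ_u V_K' + σ² I`. The data are `(Y ∘ Ω, Ω)` for a binary
revelation matrix `Ω`; observing `Ω` lets us distinguish observed zeros from
missing cells. The model is mean-zero, so no centering is performed by
default; an optional flag centres columns by their observed means for real
data whose mean structure is unknown.

Subspace error is the Davis–Kahan sin-theta loss
`L(V̂, V) = 2^{-1/2}‖V̂V̂' − VV'‖_F` — the Frobenius norm of the sines of the
principal angles, ranging over `[0, √K]` with value exactly 1 for orthogonal
lines (K = 1). A second distance, `T(V̂, V) = ‖V̂ − V W‖_{2→∞}` with `W` the
orthogonal Procrustes rotation, measures the worst single-coordinate error
after optimal alignment and is the quantity that contracts geometrically in
the noiseless theory. Both are invariant to right-orthogonal transforms of
either argument.

Every returned subspace is put in a canonical form — columns ordered by
associated eigen/singular value descending, each column's largest-magnitude
entry positive, ties broken by lowest index — purely so that repeated runs
and tests are deterministic; no statistical meaning attaches to the
convention.

## Weighted covariance initialisers

Zero-filling biases the sample second moment: diagonal entries are attenuated
by the observation probability and off-diagonal entries by the co-observation
probability. Three entrywise corrections are implemented.

* Homogeneous (OPW): estimate one observed fraction
  `p̂ = ‖Ω‖₁/(nd)` and weight by `p̂^{-1}` on the diagonal, `p̂^{-2}` off it.
  Unbiased for `n^{-1}Y'Y` under homogeneous MCAR with known `p`.
* Heterogeneous: weight entry `(j,k)` by `n` over the co-observation count of
  columns `j` and `k`. Pairs never co-observed keep weight 0 — their
  covariance entries are genuinely unidentified (see the identifiability
  obstruction below) — and a warning counts how many pairs were zeroed.
  `p̂` is never clamped; an all-missing column yields a zero covariance row
  plus a warning rather than an error.
* Grouped (OPWv): when missingness depends on the data only through a fully
  observed categorical variable, per-group OPW estimates with group-specific
  `p̂_ℓ` are combined with weights `n_ℓ/n` and embedded in a bordered
  `(d+1)×(d+1)` matrix whose top-left cell is the empirical variance of the
  category variable (the category is uncorrelated with the rest by
  construction, so the off-blocks are zero).

The initial subspace estimate is the matrix of top-K eigenvectors; inputs
are symmetrised as `(A + A')/2` before the eigensolve to absorb
floating-point asymmetry.

**Identifiability and incoherence.** If two columns are never co-observed
and the leading eigenvector concentrates on exactly those coordinates, two
orthogonal spike directions can generate identical observed-data
distributions; no estimator can recover both. The relevant difficulty
measure is the incoherence `μ(V) = √(d/K) ‖V‖_{2→∞} ∈ [1, √(d/K)]`: small
`μ` means no coordinate dominates the subspace, and the iterative algorithm
is accurate precisely in the incoherent regime. The package exposes `μ` and
the test suite demonstrates the obstruction by Monte Carlo.

## The iterative algorithm

Each iteration maps the current estimate `V` to a refined one:

1. **Screening.** Keep row `i` iff `‖ω_i‖₁ > K` (strict) and
   `σ_K(V_{J_i}) ≥ √(|J_i|/d)/σ*`, where `J_i` is the row's observed index
   set. The first condition makes the row's least-squares problem
   overdetermined; the second bounds the amplification of estimation error
   through the restricted loadings. `σ* = 3` by default — performance is
   flat in `σ*` over roughly `[2, 10]` — and a tiny relative slack (1e-9) on
   the inequality keeps exact boundary cases (e.g. fully observed rows with
   `σ* = 1`) stable under eigenvalue round-off. Screening is recomputed
   against the current iterate each iteration, which is how the supporting
   theory states the condition; a `freeze_screening` flag retains the
   initial partition instead for comparison.
2. **Imputation.** For each kept row solve
   `min_u ‖y_{i,J_i} − (V_{J_i}) u‖₂`; fill the missing coordinates with
   `V_{J_i^c} û_i` and keep observed entries bit-exactly verbatim.
3. **Projection.** Set the next estimate to the top-K right singular space
   of the imputed matrix.

Convergence is declared when the sin-theta loss between successive iterates
falls below `κ* = 1e-6` (rotation-invariant, so initialisers spanning the
same subspace give identical traces), with an iteration cap of 2000. Rows
dropped by screening never influence the fit but still receive post-hoc
minimum-norm scores for downstream use.

**Numerics.** The per-row least squares is solved in batch via the K×K
normal equations `V_{J_i}'V_{J_i} û = V_{J_i}'y` — the screened rows have
`σ_K(V_{J_i})` bounded below, so the systems are well conditioned; the
standalone per-row path uses QR with a minimum-norm pseudo-inverse fallback
on rank deficiency, and a test pins the two paths together. The top-K SVD
of the imputed matrix uses ARPACK (`scipy.sparse.linalg.svds` with a fixed
start vector, hence deterministic) when `min(n, d) ≥ 200`, LAPACK otherwise.
With `κ* = 0` and the iteration count fixed, the whole fit is a
deterministic function of `(data, V₀, config)`.

## Baselines

* **Mean imputation**: fill with 0 (the population column mean of the
  mean-zero models; observed-mean variant for real data), then a rank-K SVD.
* **Soft impute**: iterate `X ← SVT_λ(Y_Ω + X ∘ Ω^c)` with singular values
  soft-thresholded by `λ` and truncated at `rank_max` (default 20), until
  the relative Frobenius change is below `tol` (default 1e-5). The objective
  `½‖Y_Ω − X∘Ω‖_F² + λ‖X‖_*` is non-increasing across iterations and is
  asserted per iteration in tests. The oracle mode warm-starts along a
  decreasing λ grid and returns the grid point minimising the sin-theta loss
  against a known truth — a benchmark upper bound, not a practical tuner.
* **Hard impute**: the `λ = 0` limit with rank fixed at K; observed entries
  are restored exactly each iteration. It can converge to different local
  optima from different starts; this instability is documented rather than
  patched.
* **EM**: maximum likelihood for `N(μ, Σ)` under MAR. The E-step imputes
  conditional means and adds conditional covariances via Schur complements,
  grouped by missingness pattern; observed blocks are ridge-regularised by
  `1e-8 · tr(Σ)/d` (configurable). A singular system despite the ridge
  raises an explicit error — the failure mode is real and is reported, not
  silenced — and scenario runs record such replicates as excluded. The mean
  is fixed at zero in the simulation harness (the generating models are
  mean-zero); a free-mean mode exists for real data. Intended for modest
  `d`: each E-step solves per-pattern systems of the observed-block size.

## Synthetic data

The generators reproduce the benchmark study conditions and are the basis of
every test:

* **Two-spike loadings.** The fixed `d×2` matrix with column 1 flat
  (`d^{-1/2}`) and column 2 supported on the first and last quarters of the
  coordinates with entries `±(d/2)^{-1/2}`. The printed source for this
  matrix is typographically corrupted; the reconstruction uses exactly the
  entry magnitudes that are legible (`1/√500` and `±1/√250` at `d = 500`)
  with a balanced sign layout enforcing orthogonality, and the block layout
  is configurable so alternative readings can be tested. Benchmark cells
  depending on this matrix are therefore checked to ±10% rather than to
  Monte Carlo precision.
* **MCAR grids.** H1: homogeneous `P(ω=1) = 0.05`. H2: `P(ω_ij=1) = P_i Q_j`
  with `P_i ~ U[0, 0.2]`, `Q_j ~ U[0.05, 0.95]`, redrawn each replicate.
  H3: 0.19/0.01 for odd/even columns; H4: 0.18/0.02 for odd/even rows
  (1-based parity).
* **Categorical MAR.** `y₀ ~ Unif{−1, +1}` flips the data covariance between
  `V_± diag(40,10) V_±' + I` and tilts the per-column observation logit:
  `P(ω_j = 1 | y₀) = {1 + exp(j/d + y₀ α)}^{-1}`. At `α = 0` the mask is
  independent of the data. The spike matrices `V_±` default to seeded
  Haar-random `d×2` frames (their original values are not recorded in the
  source, so benchmark values for this design are treated as qualitative).
* **MNAR random walks.** Rows are d-step standard Gaussian random walks
  (covariance `min(j,k)`); entry `(i,j)` is observed iff an independent
  `Bern(p)` coin succeeds and the walk stayed strictly inside `(−τ, τ)`
  before step `j` (empty maximum convention: column 1 is never thresholded).
  Default `τ = √d`. The mechanism is MAR exactly when `p = 1` and drifts
  away from MAR as `p` decreases. The truth for this design is the leading
  eigenvector of the min(j,k) covariance.

All generators are bit-reproducible from their seed. What they do *not*
emulate: non-Gaussian heavy-tailed factors or noise, dependent missingness
across rows, and real-data mean structure — passing benchmarks here
demonstrates correctness of the algorithms under the stated models, not
robustness beyond them.

## Replication harness

`run_scenario` draws each replicate from `base_seed + replicate_index`, runs
every configured method against the generating truth, and aggregates the
per-replicate sin-theta losses as mean, `SE = sd/√reps` and
`RMSE = √(mean of squared losses)` (the benchmark tables report mean ± SE
for the MCAR studies and RMSE for the MAR/MNAR studies; the harness labels
which it used). Method failures are NaN-recorded, logged, excluded from
aggregates and counted. Results are invariant to scheduling because each
replicate's randomness derives only from its own seed.

Problem sizes in the shipped acceptance run: the MNAR table cells use the
full study size (n = 500, d = 100, 100 replicates); the noisy spiked cells
use the full data size (n = 2000, d = 500) with 10 replicates rather than
100 — the per-cell Monte Carlo SE at 10 replicates (~0.002) is already an
order of magnitude below the ±10% tolerance those cells carry for the
loading-reconstruction reason above.

## Known limitations

* K is user-supplied; no automatic rank selection.
* No standard errors or inference on the estimated loadings.
* The EM baseline scales poorly with `d` and with the number of distinct
  missingness patterns; it is a comparator, not a recommended method.
* The grouped (OPWv) estimator assumes the category is fully observed and
  the category-conditional missingness homogeneous, as in its motivating
  design.
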