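# Methods

## Model

The data tensor `X ∈ R^{n_1 × … × n_D}` (D ≥ 2, complete, real) is modeled
as `X = U* + E`, where `U*` has a checkerbox structure: binary membership
matrices `M_d ∈ {0,1}^{n_d × k_d}` with unit row sums assign each mode-d
index to one of `k_d` clusters, and `U* = C* ×_1 M_1 ×_2 … ×_D M_D` expands
a tensor `C*` of co-cluster means.  The noise `E` has independent Gaussian
entries in the synthetic models; the estimator itself makes no distributional
assumption.  Given partitions, the cell means are estimated by the sample
mean over each cell, which is the maximum-likelihood estimate under iid
Gaussian noise.

## Estimator and solver

The estimate at penalty level γ ≥ 0 is the unique minimizer of

    F_γ(u) = ½‖x − u‖² + γ Σ_d Σ_l w_{d,l} ‖A_{d,l} u‖₂ ,

in vectorized form, where `A_{d,l}` is the difference of the two mode-d
subarrays joined by edge l of the mode-d similarity graph.  The Lagrangian
dual is the ball-constrained least-squares problem

    min_λ ½‖x − Aᵀλ‖²   s.t.  ‖λ_{d,l}‖₂ ≤ γ·w_{d,l},

solved by projected gradient ascent on the dual with FISTA momentum; the
primal is recovered exactly as `û = x − Aᵀλ`.  Numerical choices:

* **Step size** — `η = 1/L` with L a 60-iteration power-iteration estimate
  of `λ_max(AAᵀ)` (seeded, matrix-free), inflated by 1% against
  underestimation.
* **Acceleration and restart** — FISTA momentum with a function-value
  restart: when the extrapolated step would decrease the dual objective, the
  iteration falls back to a plain ascent step from the current point (which
  cannot decrease it) and resets the momentum counter.  Plain projected
  gradient (monotone by construction) is available via
  `SolverConfig(accelerate=False)` and anchors the monotonicity tests.
* **Stopping** — relative duality gap `(F − G)/max(1, F) ≤ 1e-6` (the dual
  value is `G(λ) = ½‖x‖² − ½‖û‖²`), checked every 10 iterations; cap of
  20 000 iterations.  Iterates are feasible after every projection, so the
  gap is a certified optimality bound.
* **Operators** — each mode's difference map is applied through its sparse
  oriented incidence matrix acting on the mode-d matricization; dense
  Kronecker factors exist only inside test oracles.  For edge (i, j) with
  i < j the +1 lands on i.  Cost per application is linear in the data size
  per edge.
* **Warm starts** — along an ascending γ grid each solve starts from the
  previous dual solution projected onto the new feasible set.

## Weights

Adaptive weights follow a two-step construction per mode: (1) pre-weights
`w̃_{d,ij} = 1{kNN}(i,j) · exp(−τ_d · dist²(i,j))` on Frobenius distances
between mode-d subarrays of a Tucker-denoised copy of X; (2) normalization
so each mode's weights sum to `n_d / n`, keeping any single mode from
dominating the penalty.  Defaults and rationale:

* **k** — smallest k whose union k-NN graph is connected (binary search;
  connectivity is monotone in k).  Distance ties break toward the smaller
  index for determinism.
* **τ_d** — `1/m²` with m the median distance over masked pairs, so the
  kernel exponent is dimensionless; `1/m` is available as a configuration
  alternative, and τ_d = 0 gives uniform pre-weights.
* **Tucker ranks** — the shape-driven heuristic
  `min(n_d, max(2, ⌈√n_d⌉))` per mode by default; denoising is applied to
  both the k-NN indicator and the kernel (the low-rank approximation
  replaces X wholesale in the weight construction).  The Tucker
  approximation is HOOI initialized by truncated HOSVD (≤ 50 sweeps,
  relative tolerance 1e-10), implemented with numpy SVDs.
* **Theory-uniform scheme** — complete graph per mode, every weight `1/n_d`;
  this is the weighting under which the prediction-error theory is stated
  and is exposed for the theory-oriented experiments.
* Edges whose weight underflows to exactly 0 are dropped; connectivity is
  re-checked and a disconnection warning logged (the objective separates
  over components, so the fit remains valid; only full fusion to the grand
  mean is then unattainable).

## Tuning and partition extraction

`eBIC(γ) = n log(RSS_γ/n) + 2 df_γ log n` with `df_γ = Π_d k̂_d` (each cell
mean is one estimated parameter) and n the total entry count.  RSS is
floored at `1e-12 · ‖x‖²` so an exact fit stays finite; γ = 0 is excluded
from the default grid.  The default grid is geometric with 30 points from
`1e-6 · γ_max` to `γ_max`, where `γ_max` is found by doubling from 1 until
the fit collapses to the grand mean (relative deviation ≤ 1e-6), capped at
30 doublings.  The wide span (1e-6 rather than a narrower window) is
deliberate: with adaptive kernel weights the between-cluster weights are
exponentially small, so full fusion occurs orders of magnitude above the γ
at which the cluster structure appears, and the informative part of the
path sits far below `γ_max`.  Ties in the eBIC resolve toward the smaller γ.

An edge is declared *fused* when its dual block is strictly interior to its
constraint ball, `‖λ‖ ≤ (1 − δ)γw` with δ = 1e-3 — at optimality an active
difference pins its dual block to the boundary — or when its difference
norm falls below `1e-10 + 1e-8·‖x‖_F`.  The interior test is only trusted
when the ball radius is numerically resolvable (within 12 decades of the
mode's largest radius): adaptive weights can underflow so far that the dual
block is pinned near zero, which would masquerade as interiority.
Partitions are the connected components of the fused-edge graph
(breadth-first, labels canonicalized by smallest member), and co-cluster
means are cell averages of the data.

## Synthetic data

The checkerbox generator draws co-cluster means iid `Normal(0, Δ²)`
(default spread Δ = 3, truncated at |c| ≤ 50), expands them through
contiguous (optionally seeded-shuffled) balanced or explicitly sized
cluster blocks, and adds independent `Normal(0, σ²_cell)` noise with a
per-co-cluster standard-deviation map (scalar σ = homoskedastic).  The
study conditions used throughout the tests are a 20×20×20 tensor with two
clusters per mode, Δ = 3, and σ = 1 (balanced) or σ = 0.5 with per-mode
cluster sizes 16/4, i.e. an imbalance ratio of 0.2.

The CP generator places `rows_per_class` points per class on two
interleaved half-moons or on a bullseye of two concentric rings (standard
scikit-learn constructions; moon noise 0.05, ring radius ratio 0.4, ring
noise 0.05, recorded in the returned factor matrix), stacks them into
`A ∈ R^{2m × 2}`, forms the symmetric rank-2 tensor
`U* = a_1∘a_1∘a_1 + a_2∘a_2∘a_2` from the columns of A, and adds iid
Gaussian noise.  This mean structure is deliberately *not* a checkerbox —
it probes behavior under model misspecification with non-convex classes.

What the generators do not emulate: dependent or heavy-tailed noise,
missing entries (the method requires complete data; imputation is upstream
and out of scope), and non-block mean structure beyond the rank-2 CP
family.  Passing tests therefore demonstrate correctness of the estimator
and its implementation under these stated conditions, not robustness to
arbitrary real-data pathologies.

## Baselines

CPD+k-means: rank-R CP decomposition by alternating least squares (3 seeded
starts, ≤ 200 sweeps, relative-fit tolerance 1e-7; rank candidates
{2,3,4,5} when R is "auto", chosen by best fit), then k-means (10 restarts,
seeded) on the rows of each factor matrix.  CoTeC: k-means directly on the
rows of each mode's matricization.  When k is "auto" it is chosen per mode
by the Tibshirani gap statistic with a uniform bounding-box reference
(B = 10 draws, smallest k with `gap(k) ≥ gap(k+1) − s_{k+1}`; constant
features return 1).

## Problem sizes in the validation runs

The test suite and acceptance script run at desk scale, chosen so every
property is exercised on sizes where the reference oracles are exact:
solver-vs-oracle comparisons on tensors up to 4×4×3 (dense ADMM with 3000
iterations as the independent minimizer); recovery experiments at 20³ (20
replicates per setting in the tests, 10 in the script); the size trend on
10³/15³/20³; and the CP bullseye contrast at 15 rows per class (a 30³
tensor; the generator's default of 40 rows per class produces an 80³ tensor
whose full path costs minutes per replicate and adds nothing to the
qualitative contrast).

## Known limitations

* The dual solver's convergence rate degrades near the fusion threshold of
  large, weakly separated problems; warm starts mitigate this along grids.
* eBIC with `df = Π k̂_d` can prefer the fully fused model when the true
  mean structure is far from a checkerbox (seen on the bullseye model at
  some seeds), since no grid point offers a small-RSS/small-df compromise.
* Exact k-NN distances cost O(n_d² · n_{-d}) per mode; adequate at desk
  scale, but approximate neighbor search would be needed for very long
  modes.
* The theory-uniform weighting is exposed for completeness but is known to
  recover structure less well than adaptive weights; the package's defaults
  are the adaptive scheme.
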