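# cococlust — convex co-clustering of multiway tensors

`cococlust` simultaneously clusters a complete real-valued data tensor
`X ∈ R^{n_1 × … × n_D}` along **all** of its modes.  It is aimed at settings
where the mean structure is a *checkerbox*: each mode-d index belongs to one
of `k_d` clusters, and every cell of the cross-product partition shares a
single mean — the D-way generalization of checkerboard biclustering
(omics matrices, exposure × time × region rate tensors, user × item ×
context interaction tensors, …).

## The estimator

Co-cluster assignments and cell means are estimated jointly as the unique
minimizer of the strongly convex objective

    F_γ(U) = ½ ‖X − U‖_F² + γ Σ_d Σ_{(i,j)∈E_d} w_{d,ij} ‖U ×_d (e_iᵀ − e_jᵀ)‖_F ,

an ℓ₂ fusion penalty on pairwise differences of mode-d subarrays over sparse
per-mode similarity graphs `E_d` with weights `w_{d,ij}`.  As γ grows, mode-d
subarrays coalesce exactly; the solution path sweeps from `U = X` (γ = 0) to
the grand-mean tensor (full fusion).  The problem is solved through its
Lagrangian dual — a ball-constrained least-squares program — by accelerated
projected gradient, with the primal recovered exactly as
`Û = X − Aᵀλ̂`.  Partitions are read off the fused differences by connected
components; γ is selected on a grid by the extended BIC

    eBIC(γ) = n · log(RSS_γ / n) + 2 · df_γ · log(n),   df_γ = Π_d k̂_d .

Weights are data-adaptive: union k-nearest-neighbour sparsification and a
Gaussian kernel on subarray distances computed from a Tucker-denoised copy
of `X`, normalized per mode.  Synthetic generators (checkerbox with
imbalance and heteroskedasticity; rank-2 symmetric CP tensors with
half-moon / bullseye factor geometry) and two k-means baselines
(CPD+k-means, per-mode CoTeC) are included for validation.

## Worked example

```python
import numpy as np
from cococlust import (CheckerboxSpec, simulate_checkerbox, build_weights,
                       fit_path, adjusted_rand_index)

spec = CheckerboxSpec(shape=(20, 20, 20), clusters=(2, 2, 2),
                      mean_spread=3.0, sigma=1.0, seed=0)
X, U_true, labels_true = simulate_checkerbox(spec)

graph = build_weights(X)              # adaptive Tucker/Gaussian weights
sel = fit_path(X, graph, grid_size=20)  # warm-started path + eBIC selection

clust = sel.selected_clustering
print("selected gamma:", round(sel.selected_gamma, 1))
print("cluster counts:", clust.cluster_counts)
print("per-mode ARI:  ", [adjusted_rand_index(clust.labels[d], labels_true[d])
                          for d in range(3)])
```

Output:

```
selected gamma: 81447.4
cluster counts: (2, 2, 2)
per-mode ARI:   [1.0, 1.0, 1.0]
```

The fit recovers the generative two-clusters-per-mode checkerbox exactly
(adjusted Rand index 1 in every mode) at the eBIC-selected penalty level.

The same pipeline is available from the shell:

```sh
cococlust simulate --model checkerbox --shape 20,20,20 --sigma 1.0 --out sim/
cococlust path sim/tensor.npy --out run/
cococlust evaluate run/ sim/ --stem-b true_labels
```

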