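"""Partition extraction from a fitted estimate and clustering evaluation.

Two mode-d subarrays belong to the same cluster when their estimated
difference block is (numerically) zero.  Because iterates carry finite-
precision error, an edge is declared *fused* when its dual block sits
strictly inside its constraint ball (the signature of a vanished difference
at optimality) or its primal difference norm is negligible.  Clusters are the
connected components of the fused-edge graph; co-cluster means are sample
means of the data over each cell of the induced checkerbox.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _scipy_cc
from sklearn.metrics import adjusted_rand_score

from .dual_solver import CoCoFit
from .mode_graphs import ModeGraph
from .tensor_core import as_array, frobenius_norm

__all__ = [
    "CoClustering",
    "fused_edges",
    "connected_components",
    "co_cluster_means",
    "extract_partitions",
    "adjusted_rand_index",
    "count_co_clusters",
]


@dataclass
class CoClustering:
    """Hard per-mode partitions plus the implied co-cluster means.

    ``labels[d-1]`` holds 1-based labels (1..k_d) canonicalized by first
    occurrence; ``means`` is the k_1 x ... x k_D tensor of cell averages.
    """

    labels: list[np.ndarray]
    means: np.ndarray

    @property
    def cluster_counts(self) -> tuple[int, ...]:
        return tuple(int(lab.max()) for lab in self.labels)

    def membership_matrices(self) -> list[np.ndarray]:
        """Binary n_d x k_d matrices with unit row sums."""
        out = []
        for lab in self.labels:
            M = np.zeros((len(lab), int(lab.max())), dtype=int)
            M[np.arange(len(lab)), lab - 1] = 1
            out.append(M)
        return out


def fused_edges(
    fit: CoCoFit,
    graph: ModeGraph | None = None,
    delta: float = 1e-3,
    eps_rel: float = 1e-8,
    eps_abs: float = 1e-10,
    x=None,
) -> list[np.ndarray]:
    """Boolean per-mode arrays marking which graph edges are fused.

    Edge l of mode d is fused iff its dual block is strictly interior,
    ||lambda_{d,l}|| <= (1 - delta) * gamma * w_{d,l}, or its difference norm
    satisfies ||v_{d,l}|| <= eps_abs + eps_rel * ||x||_F.  The interior test
    is only trusted on edges whose ball radius is numerically resolvable
    (within 12 decades of the mode's largest radius): a radius that has
    underflowed to the subnormal range pins the dual block to zero, which
    would masquerade as strict interiority.  At gamma = 0 no edge is fused
    by convention.
    """
    graph = graph or fit.graph
    if fit.gamma == 0.0:
        return [np.zeros(len(w), dtype=bool) for w in graph.weights]
    xnorm = frobenius_norm(x) if x is not None else float(np.linalg.norm(fit.u))
    thresh = eps_abs + eps_rel * xnorm
    out = []
    for w, dn, ln in zip(graph.weights, fit.diff_norms, fit.dual_norms):
        radius = fit.gamma * w
        resolvable = radius > 1e-12 * (radius.max() if len(radius) else 0.0)
        interior = (ln <= (1.0 - delta) * radius) & resolvable
        tiny = dn <= thresh
        out.append(interior | tiny)
    return out


def connected_components(n_d: int, edges) -> np.ndarray:
    """1-based component labels for nodes 1..n_d joined by the given 0-based
    edge pairs; labels canonicalized by smallest member index."""
    E = np.asarray(list(edges), dtype=int).reshape(-1, 2)
    if E.size and (E.min() < 0 or E.max() >= n_d):
        raise ValueError("edge endpoints out of range")
    g = coo_matrix(
        (np.ones(len(E)), (E[:, 0], E[:, 1])), shape=(n_d, n_d)
    )
    _, raw = _scipy_cc(g, directed=False)
    # relabel so components are numbered by their smallest member
    remap: dict[int, int] = {}
    labels = np.empty(n_d, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    return labels


def co_cluster_means(X, labels: list[np.ndarray]) -> np.ndarray:
    """Tensor of sample means of ``X`` over each co-cluster cell."""
    arr = as_array(X)
    if len(labels) != arr.ndim:
        raise ValueError("one label array per mode is required")
    counts = tuple(int(np.max(lab)) for lab in labels)
    sums = np.zeros(counts)
    cnt = np.zeros(counts)
    idx = np.meshgrid(*[lab - 1 for lab in labels], indexing="ij")
    np.add.at(sums, tuple(idx), arr)
    np.add.at(cnt, tuple(idx), 1.0)
    return sums / cnt


def extract_partitions(
    fit: CoCoFit,
    X=None,
    graph: ModeGraph | None = None,
    **fuse_kwargs,
) -> CoClustering:
    """Turn a fit into hard per-mode partitions and co-cluster means.

    Means are computed from the data tensor ``X`` when supplied (the maximum
    likelihood estimate given the partitions), otherwise from the fit itself.
    """
    graph = graph or fit.graph
    fused = fused_edges(fit, graph, x=X, **fuse_kwargs)
    labels = [
        connected_components(graph.shape[d], graph.edges[d][fused[d]])
        for d in range(graph.order)
    ]
    source = as_array(X) if X is not None else fit.tensor
    return CoClustering(labels=labels, means=co_cluster_means(source, labels))


def count_co_clusters(labels: list[np.ndarray]) -> int:
    """Number of cells of the checkerbox implied by per-mode partitions,
    prod_d k_d — the degrees of freedom of the fitted mean model."""
    return int(np.prod([int(np.max(lab)) for lab in labels]))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings; 1 for a
    perfect match, about 0 for chance-level agreement."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if a.size < 2:
        raise ValueError("need at least two elements")
    return float(adjusted_rand_score(a, b))
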