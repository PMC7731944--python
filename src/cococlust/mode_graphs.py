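"""Per-mode similarity graphs and fusion weights.

The fusion penalty needs, for every mode d, a sparse weighted graph on the
mode-d subarrays.  The adaptive construction is:

1. (optional) denoise the tensor with a low-rank Tucker approximation;
2. pairwise Frobenius distances between mode-d subarrays;
3. sparsify to a union k-nearest-neighbour graph (smallest connecting k by
   default);
4. Gaussian-kernel pre-weights ``exp(-tau_d * dist^2)`` with the inverse
   scale set from the median masked distance;
5. normalize each mode's weights to sum to ``n_d / n`` so no single mode
   dominates the penalty.

The theory-uniform scheme instead takes the complete graph per mode with every
weight equal to ``1/n_d``, the convention under which the prediction-error
theory is stated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial.distance import pdist, squareform

from .tensor_core import as_array, matricize, mode_product

logger = logging.getLogger(__name__)

__all__ = [
    "ModeGraph",
    "WeightConfig",
    "DegenerateScaleError",
    "pairwise_mode_distances",
    "knn_mask",
    "smallest_connected_k",
    "median_scale",
    "gaussian_preweights",
    "normalize_mode_weights",
    "tucker_denoise",
    "build_weights",
]


class DegenerateScaleError(ValueError):
    """All masked pairwise distances are zero, so no kernel scale exists."""


@dataclass
class ModeGraph:
    """Weighted edge lists for all modes of one tensor.

    ``edges[d]`` is an (m_d, 2) integer array of 0-based pairs with i < j and
    ``weights[d]`` the aligned strictly positive weights.  ``normalized``
    marks the adaptive scheme (per-mode sums n_d/n); ``theory_uniform`` marks
    the complete-graph 1/n_d scheme.
    """

    shape: tuple[int, ...]
    edges: list[np.ndarray]
    weights: list[np.ndarray]
    normalized: bool = False
    theory_uniform: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def order(self) -> int:
        return len(self.shape)

    def is_connected(self, d: int) -> bool:
        """Whether the mode-d graph (1-based d) has a single component."""
        nd = self.shape[d - 1]
        E = self.edges[d - 1]
        if nd == 1:
            return True
        g = coo_matrix(
            (np.ones(len(E)), (E[:, 0], E[:, 1])), shape=(nd, nd)
        )
        ncomp, _ = _cc(g, directed=False)
        return ncomp == 1


@dataclass
class WeightConfig:
    """Configuration of the weight construction.

    Parameters
    ----------
    k : per-mode neighbour count; "auto" picks the smallest connecting k.
    tau : per-mode inverse squared scale; "auto-median" sets 1/m^2 with m the
        median masked distance ("inverse-median" selects the 1/m alternative;
        an explicit 0 yields uniform pre-weights on the mask).
    tucker_ranks : per-mode Tucker ranks for denoising, "auto" for the
        shape-driven heuristic ``min(n_d, max(2, ceil(sqrt(n_d))))``, or
        "off" to skip denoising.
    scheme : "adaptive" | "theory-uniform".
    """

    k: int | str | list = "auto"
    tau: float | str | list = "auto-median"
    tucker_ranks: str | tuple | None = "auto"
    scheme: str = "adaptive"

    def per_mode(self, value, D: int) -> list:
        if isinstance(value, (list, tuple)):
            if len(value) != D:
                raise ValueError(f"expected {D} per-mode values, got {len(value)}")
            return list(value)
        return [value] * D


def pairwise_mode_distances(T, d: int) -> np.ndarray:
    """Symmetric n_d x n_d matrix of Frobenius distances between the mode-d
    subarrays (rows of the mode-d matricization)."""
    M = matricize(T, d)
    if M.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(M, metric="euclidean"))


def knn_mask(distances: np.ndarray, k: int) -> np.ndarray:
    """Union k-nearest-neighbour mask: (i, j) is true iff j is among i's k
    nearest or i among j's k nearest.  Distance ties break by smaller index
    (numpy stable argsort), the diagonal is always false."""
    D = np.asarray(distances)
    nd = D.shape[0]
    if not 1 <= k <= nd - 1:
        raise ValueError(f"k={k} out of range 1..{nd - 1}")
    order = np.argsort(D + np.diag(np.full(nd, np.inf)), axis=1, kind="stable")
    mask = np.zeros((nd, nd), dtype=bool)
    rows = np.repeat(np.arange(nd), k)
    mask[rows, order[:, :k].ravel()] = True
    mask |= mask.T
    np.fill_diagonal(mask, False)
    return mask


def _mask_connected(mask: np.ndarray) -> bool:
    g = coo_matrix(mask)
    ncomp, _ = _cc(g, directed=False)
    return ncomp == 1


def smallest_connected_k(distances: np.ndarray) -> int:
    """Minimal k for which the union k-NN graph is connected.

    Connectivity is monotone in k (larger k only adds edges), so a binary
    search over 1..n_d-1 suffices; k = n_d - 1 always connects.
    """
    nd = np.asarray(distances).shape[0]
    if nd < 2:
        raise ValueError("need at least two mode-d subarrays")
    lo, hi = 1, nd - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if _mask_connected(knn_mask(distances, mid)):
            hi = mid
        else:
            lo = mid + 1
    return lo


def median_scale(
    distances: np.ndarray, mask: np.ndarray, convention: str = "inverse-median-squared"
) -> float:
    """Inverse kernel scale tau_d from the median masked distance m.

    The default convention returns ``1/m^2`` (dimensionless exponent in the
    Gaussian kernel); ``"inverse-median"`` returns ``1/m``.
    """
    iu = np.triu_indices_from(mask, k=1)
    vals = np.asarray(distances)[iu][np.asarray(mask)[iu]]
    if vals.size == 0:
        raise ValueError("mask selects no pairs")
    m = float(np.median(vals))
    if m == 0.0:
        raise DegenerateScaleError("median masked distance is zero")
    if convention == "inverse-median-squared":
        return 1.0 / m**2
    if convention == "inverse-median":
        return 1.0 / m
    raise ValueError(f"unknown convention {convention!r}")


def gaussian_preweights(
    distances: np.ndarray, mask: np.ndarray, tau: float
) -> np.ndarray:
    """Pre-weights ``mask * exp(-tau * dist^2)``; tau = 0 gives uniform
    weights on the masked pairs."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    return np.where(mask, np.exp(-tau * np.asarray(distances) ** 2), 0.0)


def normalize_mode_weights(w_tilde: np.ndarray, n_d: int, n: int) -> np.ndarray:
    """Rescale pre-weights so the mode's weights sum to ``n_d / n``."""
    total = float(np.sum(w_tilde))
    if total <= 0:
        raise ValueError("pre-weights sum to zero; nothing to normalize")
    return np.asarray(w_tilde) * ((n_d / n) / total)


def _hosvd_factors(X: np.ndarray, ranks: tuple[int, ...]) -> list[np.ndarray]:
    return [
        np.linalg.svd(matricize(X, d + 1), full_matrices=False)[0][:, : ranks[d]]
        for d in range(X.ndim)
    ]


def _multi_mode_product(X: np.ndarray, mats: list[np.ndarray], transpose=False):
    out = X
    for d, U in enumerate(mats, start=1):
        out = mode_product(out, U.T if transpose else U, d)
    return out


def tucker_denoise(T, ranks, n_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Rank-(r_1, ..., r_D) Tucker approximation of ``T``.

    Higher-order orthogonal iteration (HOOI) initialized by the truncated
    higher-order SVD; returns a tensor of identical shape.
    """
    X = as_array(T)
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != X.ndim or any(
        not 1 <= r <= s for r, s in zip(ranks, X.shape)
    ):
        raise ValueError(f"invalid Tucker ranks {ranks} for shape {X.shape}")
    U = _hosvd_factors(X, ranks)
    if all(r == s for r, s in zip(ranks, X.shape)):
        return X.copy()
    prev = np.inf
    for _ in range(n_iter):
        for d in range(X.ndim):
            Y = X
            for j, Uj in enumerate(U, start=1):
                if j != d + 1:
                    Y = mode_product(Y, Uj.T, j)
            U[d] = np.linalg.svd(matricize(Y, d + 1), full_matrices=False)[0][
                :, : ranks[d]
            ]
        core = _multi_mode_product(X, U, transpose=True)
        fit = float(np.linalg.norm(core.ravel()))
        if abs(fit - prev) <= tol * max(1.0, fit):
            break
        prev = fit
    core = _multi_mode_product(X, U, transpose=True)
    return _multi_mode_product(core, U)


def default_tucker_ranks(shape: tuple[int, ...]) -> tuple[int, ...]:
    """Shape-driven heuristic: ``min(n_d, max(2, ceil(sqrt(n_d))))``."""
    return tuple(min(s, max(2, int(np.ceil(np.sqrt(s))))) for s in shape)


def _mask_to_edges(values: np.ndarray, mask: np.ndarray):
    iu = np.triu_indices_from(mask, k=1)
    keep = mask[iu] & (values[iu] > 0)
    edges = np.stack([iu[0][keep], iu[1][keep]], axis=1)
    return edges, values[iu][keep]


def build_weights(T, config: WeightConfig | None = None) -> ModeGraph:
    """Run the full weight-construction pipeline for every mode."""
    X = as_array(T)
    D = X.ndim
    n = X.size
    config = config or WeightConfig()

    if config.scheme == "theory-uniform":
        edges, weights = [], []
        for nd in X.shape:
            iu = np.triu_indices(nd, k=1)
            edges.append(np.stack(iu, axis=1))
            weights.append(np.full(len(iu[0]), 1.0 / nd))
        return ModeGraph(X.shape, edges, weights, theory_uniform=True)
    if config.scheme != "adaptive":
        raise ValueError(f"unknown scheme {config.scheme!r}")

    ranks_cfg = config.tucker_ranks
    if ranks_cfg in (None, "off"):
        Xd = X
        ranks_used = None
    else:
        ranks_used = (
            default_tucker_ranks(X.shape) if ranks_cfg == "auto" else tuple(ranks_cfg)
        )
        Xd = tucker_denoise(X, ranks_used)

    ks = config.per_mode(config.k, D)
    taus = config.per_mode(config.tau, D)
    edges, weights, meta = [], [], {"tucker_ranks": ranks_used, "k": [], "tau": []}
    for d in range(1, D + 1):
        nd = X.shape[d - 1]
        dist = pairwise_mode_distances(Xd, d)
        k = smallest_connected_k(dist) if ks[d - 1] == "auto" else int(ks[d - 1])
        mask = knn_mask(dist, k)
        tau_cfg = taus[d - 1]
        if tau_cfg == "auto-median":
            try:
                tau = median_scale(dist, mask)
            except DegenerateScaleError:
                tau = 0.0
        elif tau_cfg == "inverse-median":
            try:
                tau = median_scale(dist, mask, convention="inverse-median")
            except DegenerateScaleError:
                tau = 0.0
        else:
            tau = float(tau_cfg)
        w_tilde = gaussian_preweights(dist, mask, tau)
        # normalize over the unordered pairs (upper triangle), which are the
        # penalty terms; the symmetric matrix double-counts each pair
        E_all, wt = _mask_to_edges(w_tilde, mask)
        wv = normalize_mode_weights(wt, nd, n)
        E = E_all
        edges.append(E)
        weights.append(wv)
        meta["k"].append(k)
        meta["tau"].append(tau)
    graph = ModeGraph(X.shape, edges, weights, normalized=True, meta=meta)
    for d in range(1, D + 1):
        if not graph.is_connected(d):
            # the objective separates over components; downstream full fusion
            # then stops at one cluster per component instead of one overall
            warnings.warn(f"mode-{d} similarity graph is disconnected")
            logger.warning("mode-%d similarity graph is disconnected", d)
    return graph
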