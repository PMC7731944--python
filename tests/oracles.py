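"""Independent brute-force oracles used across the test suite.

Everything here deliberately avoids the package's fast paths: dense Kronecker
matrices are materialized explicitly, and the fusion-penalized problem is
minimized by a generic dense ADMM rather than the dual projected-gradient
solver under test.
"""

from functools import reduce

import numpy as np

from cococlust import vectorize
from cococlust.mode_graphs import ModeGraph


def dense_edge_matrix(shape, d, i, j):
    """Dense n_{-d} x n matrix  I_{n_D} (x) ... (x) Delta_{d,ij} (x) ... (x) I_{n_1}
    with Delta = e_i^T - e_j^T (0-based i, j)."""
    mats = []
    for mode in range(len(shape), 0, -1):
        if mode == d:
            eye = np.eye(shape[d - 1])
            mats.append(eye[[i]] - eye[[j]])
        else:
            mats.append(np.eye(shape[mode - 1]))
    return reduce(np.kron, mats)


def dense_mode_product_matrix(shape, B, d):
    """Dense matrix representing vec(T x_d B) = M @ vec(T)."""
    mats = []
    for mode in range(len(shape), 0, -1):
        mats.append(B if mode == d else np.eye(shape[mode - 1]))
    return reduce(np.kron, mats)


def dense_blocks(graph: ModeGraph):
    """All edge-difference blocks of a graph as dense matrices, with their
    weights, ordered mode-major then edge-major."""
    blocks, weights = [], []
    for d in range(1, graph.order + 1):
        for (i, j), w in zip(graph.edges[d - 1], graph.weights[d - 1]):
            blocks.append(dense_edge_matrix(graph.shape, d, i, j))
            weights.append(w)
    return blocks, np.asarray(weights)


def admm_primal_minimizer(x, graph: ModeGraph, gamma, rho=1.0, iters=4000):
    """Generic dense ADMM minimizer of the fusion-penalized objective.

    Splits v_b = A_b u; the u-update is a prefactorized dense solve and the
    v-update a per-block group soft-threshold.  Independent of the dual
    projected-gradient path.
    """
    x = vectorize(x)
    n = x.size
    blocks, w = dense_blocks(graph)
    if not blocks:
        return x.copy()
    A = np.vstack(blocks)
    sizes = [b.shape[0] for b in blocks]
    starts = np.cumsum([0] + sizes)
    M = np.linalg.inv(np.eye(n) + rho * A.T @ A)
    v = np.zeros(A.shape[0])
    y = np.zeros(A.shape[0])
    for _ in range(iters):
        u = M @ (x + rho * A.T @ (v - y))
        Au = A @ u
        z = Au + y
        for b in range(len(blocks)):
            s = slice(starts[b], starts[b + 1])
            zb = z[s]
            kappa = gamma * w[b] / rho
            nrm = np.linalg.norm(zb)
            v[s] = 0.0 if nrm <= kappa else (1.0 - kappa / nrm) * zb
        y += Au - v
    return u


def ari_contingency(a, b):
    """Hubert-Arabie adjusted Rand index straight from the contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)))
    for i, j in zip(ia, ib):
        table[i, j] += 1

    def comb2(m):
        return m * (m - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(len(a))
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
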