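"""Synthetic tensors with known co-cluster ground truth.

Two generative families are provided:

* the **checkerbox model** — a block-constant mean tensor expanded from a
  small tensor of co-cluster means through binary per-mode membership
  matrices, plus independent Gaussian noise whose standard deviation may vary
  per co-cluster (heteroskedasticity) and whose per-mode cluster sizes may be
  imbalanced;
* a **rank-2 symmetric CP model** whose factor matrix rows trace a non-convex
  planar shape (two interleaved half-moons, or a bullseye of concentric
  rings), a deliberately misspecified mean structure with no checkerbox
  pattern.

All randomness flows through a single seed for bit-reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.datasets import make_circles, make_moons

from .tensor_core import mode_product

__all__ = [
    "CheckerboxSpec",
    "CPShapeSpec",
    "expand_means",
    "simulate_checkerbox",
    "simulate_cp_shapes",
]

MEAN_BOUND = 50.0  # |c*| cap enforced on sampled co-cluster means


@dataclass
class CheckerboxSpec:
    """Description of one checkerbox simulation.

    ``cluster_sizes`` overrides balanced sizes per mode (each list must sum to
    n_d).  ``means`` fixes the co-cluster means tensor explicitly; otherwise
    they are drawn iid Normal(0, mean_spread^2), truncated to +-50.  ``sigma``
    is either a scalar (homoskedastic) or a k_1 x ... x k_D array of
    per-co-cluster noise standard deviations.  ``shuffle`` applies a seeded
    permutation along every mode so cluster blocks are not contiguous.
    """

    shape: tuple[int, ...]
    clusters: tuple[int, ...]
    cluster_sizes: list[list[int]] | None = None
    means: np.ndarray | None = None
    mean_spread: float = 3.0
    sigma: float | np.ndarray = 1.0
    shuffle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != len(self.clusters):
            raise ValueError("shape and clusters must have equal length")
        if any(k < 1 or k > s for k, s in zip(self.clusters, self.shape)):
            raise ValueError("each mode needs 1 <= k_d <= n_d")
        if self.cluster_sizes is not None:
            for sizes, nd, kd in zip(self.cluster_sizes, self.shape, self.clusters):
                if len(sizes) != kd or sum(sizes) != nd or min(sizes) < 1:
                    raise ValueError(
                        f"cluster sizes {sizes} incompatible with n_d={nd}, k_d={kd}"
                    )


def _balanced_sizes(nd: int, kd: int) -> list[int]:
    base = nd // kd
    sizes = [base] * kd
    for i in range(nd - base * kd):
        sizes[i] += 1
    return sizes


def _memberships(spec: CheckerboxSpec) -> list[np.ndarray]:
    out = []
    for d, (nd, kd) in enumerate(zip(spec.shape, spec.clusters)):
        sizes = (
            spec.cluster_sizes[d] if spec.cluster_sizes is not None
            else _balanced_sizes(nd, kd)
        )
        labels = np.repeat(np.arange(kd), sizes)
        M = np.zeros((nd, kd), dtype=int)
        M[np.arange(nd), labels] = 1
        out.append(M)
    return out


def expand_means(C: np.ndarray, memberships: list[np.ndarray]) -> np.ndarray:
    """Expand a co-cluster means tensor through binary membership matrices:
    ``U* = C x_1 M_1 x_2 ... x_D M_D``, so every entry equals the mean of
    its cell."""
    C = np.asarray(C, dtype=float)
    if len(memberships) != C.ndim:
        raise ValueError("one membership matrix per mode is required")
    out = C
    for d, M in enumerate(memberships, start=1):
        M = np.asarray(M)
        if M.ndim != 2 or not np.all(M.sum(axis=1) == 1) or not np.isin(M, (0, 1)).all():
            raise ValueError("membership matrices must be binary with unit row sums")
        out = mode_product(out, M, d)
    return out


def simulate_checkerbox(spec: CheckerboxSpec):
    """Draw one tensor from the checkerbox model.

    Returns ``(X, U_star, labels)`` where ``labels[d]`` are the 1-based true
    mode-d cluster assignments aligned with the expansion that built U*.
    """
    rng = np.random.default_rng(spec.seed)
    memberships = _memberships(spec)
    if spec.means is not None:
        C = np.asarray(spec.means, dtype=float)
        if C.shape != tuple(spec.clusters):
            raise ValueError("means tensor shape must equal the cluster counts")
    else:
        C = np.clip(
            rng.normal(0.0, spec.mean_spread, size=spec.clusters),
            -MEAN_BOUND, MEAN_BOUND,
        )
    U = expand_means(C, memberships)
    sigma = np.asarray(spec.sigma, dtype=float)
    if sigma.ndim == 0:
        sigma_cell = np.full(spec.clusters, float(sigma))
    else:
        if sigma.shape != tuple(spec.clusters):
            raise ValueError("sigma array must have one value per co-cluster")
        sigma_cell = sigma
    if np.any(sigma_cell < 0):
        raise ValueError("noise standard deviations must be nonnegative")
    labels = [np.argmax(M, axis=1) + 1 for M in memberships]
    sigma_full = expand_means(sigma_cell, memberships)
    X = U + rng.standard_normal(U.shape) * sigma_full
    if spec.shuffle:
        for d in range(len(spec.shape)):
            perm = rng.permutation(spec.shape[d])
            X = np.take(X, perm, axis=d)
            U = np.take(U, perm, axis=d)
            labels[d] = labels[d][perm]
    return X, U, labels


@dataclass
class CPShapeSpec:
    """Rank-2 symmetric CP simulation from a planar point shape.

    ``rows_per_class`` points are drawn for each of the two classes; the
    stacked 2-column factor matrix A (class 1 first) defines the mean tensor
    ``U* = a_1 o a_1 o a_1 + a_2 o a_2 o a_2`` from the *columns* of A, and
    iid Normal(0, sigma^2) noise is added.
    """

    shape_name: str = "halfmoons"
    rows_per_class: int = 40
    sigma: float = 0.1
    seed: int = 0
    # shape geometry, recorded in output metadata
    moon_noise: float = 0.05
    bullseye_factor: float = 0.4
    bullseye_noise: float = 0.05

    def __post_init__(self) -> None:
        if self.shape_name not in ("halfmoons", "bullseye"):
            raise ValueError("shape_name must be 'halfmoons' or 'bullseye'")
        if self.rows_per_class < 1:
            raise ValueError("rows_per_class must be positive")


def _shape_points(spec: CPShapeSpec) -> tuple[np.ndarray, np.ndarray]:
    m = spec.rows_per_class
    seed = int(spec.seed) % (2**31)
    if spec.shape_name == "halfmoons":
        pts, lab = make_moons(n_samples=(m, m), noise=spec.moon_noise,
                              random_state=seed, shuffle=False)
    else:
        pts, lab = make_circles(n_samples=(m, m), noise=spec.bullseye_noise,
                                factor=spec.bullseye_factor,
                                random_state=seed, shuffle=False)
    # class 1 occupies the first block of rows
    order = np.argsort(lab, kind="stable")
    return pts[order], lab[order] + 1


def simulate_cp_shapes(spec: CPShapeSpec):
    """Draw one tensor from the rank-2 symmetric CP model.

    Returns ``(X, labels, A)`` with ``labels`` the two-class row assignment
    (rows 1..m are class 1) shared by all three modes, and ``A`` the
    (2m x 2) factor matrix.
    """
    A, labels = _shape_points(spec)
    a1, a2 = A[:, 0], A[:, 1]
    U = np.einsum("i,j,k->ijk", a1, a1, a1) + np.einsum("i,j,k->ijk", a2, a2, a2)
    rng = np.random.default_rng(spec.seed)
    X = U + rng.standard_normal(U.shape) * spec.sigma
    return X, labels, A
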