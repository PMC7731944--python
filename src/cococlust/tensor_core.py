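"""Tensor containers and the linear-algebra primitives used throughout.

Conventions
-----------
A *D*-way tensor with shape ``(n_1, ..., n_D)`` is stored as a plain numpy
array.  Its **vectorization** is the column-major (Fortran-order) flattening,
which coincides with the column-major flattening of the mode-1 matricization.
The **mode-d matricization** rearranges the tensor so that its mode-d fibers
become the columns of an ``n_d x n_{-d}`` matrix, with ``n_{-d} = prod_{j != d}
n_j`` and the remaining modes ordered ``1, ..., d-1, d+1, ..., D`` (the
canonical unfolding of Kolda & Bader).

Modes are 1-based in every public signature, matching the standard notation
for d-mode products; numpy axes are derived internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DataTensor",
    "DifferenceOperator",
    "vectorize",
    "unvectorize",
    "matricize",
    "dematricize",
    "mode_product",
    "frobenius_norm",
    "build_difference_operator",
]


@dataclass(frozen=True)
class DataTensor:
    """A dense, complete, real-valued tensor of order D >= 2.

    Thin wrapper around a numpy array that validates finiteness and order.
    Most functions in this package accept either a ``DataTensor`` or a bare
    ``ndarray``; use :func:`as_array` to normalize.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim < 2:
            raise ValueError(f"tensor order must be >= 2, got {arr.ndim}")
        if any(s < 1 for s in arr.shape):
            raise ValueError(f"every mode length must be >= 1, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("tensor entries must all be finite")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def order(self) -> int:
        return self.values.ndim

    @property
    def n(self) -> int:
        return self.values.size


def as_array(T) -> np.ndarray:
    """Return the underlying ndarray of a DataTensor (or pass arrays through)."""
    if isinstance(T, DataTensor):
        return T.values
    return np.asarray(T, dtype=float)


def vectorize(T) -> np.ndarray:
    """Column-major vectorization: entry (i_1, ..., i_D) lands at linear
    position ``i_1 + sum_{d>=2} (i_d - 1) * prod_{j<d} n_j`` (1-based)."""
    return as_array(T).reshape(-1, order="F")


def unvectorize(u: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`vectorize` for the given shape."""
    return np.asarray(u, dtype=float).reshape(shape, order="F")


def _check_mode(d: int, order: int) -> int:
    if not 1 <= d <= order:
        raise ValueError(f"mode index d={d} out of range 1..{order}")
    return d - 1


def matricize(T, d: int) -> np.ndarray:
    """Mode-d matricization: columns are the mode-d fibers of ``T``."""
    arr = as_array(T)
    ax = _check_mode(d, arr.ndim)
    return np.moveaxis(arr, ax, 0).reshape(arr.shape[ax], -1, order="F")


def dematricize(M: np.ndarray, shape: tuple[int, ...], d: int) -> np.ndarray:
    """Inverse of :func:`matricize`: fold an ``n_d x n_{-d}`` matrix back."""
    ax = _check_mode(d, len(shape))
    folded_shape = (shape[ax],) + tuple(s for j, s in enumerate(shape) if j != ax)
    folded = np.asarray(M, dtype=float).reshape(folded_shape, order="F")
    return np.moveaxis(folded, 0, ax)


def mode_product(T, B: np.ndarray, d: int) -> np.ndarray:
    """d-mode product ``T x_d B``: multiply every mode-d fiber by ``B``.

    ``B`` is ``m x n_d``; the result has mode-d length ``m`` and the other
    modes unchanged.  Its mode-d matricization is ``B @ matricize(T, d)``.
    """
    arr = as_array(T)
    B = np.asarray(B, dtype=float)
    ax = _check_mode(d, arr.ndim)
    if B.ndim != 2 or B.shape[1] != arr.shape[ax]:
        raise ValueError(
            f"matrix of shape {B.shape} cannot multiply mode {d} of length {arr.shape[ax]}"
        )
    new_shape = arr.shape[:ax] + (B.shape[0],) + arr.shape[ax + 1:]
    return dematricize(B @ matricize(arr, d), new_shape, d)


def frobenius_norm(T) -> float:
    """Square root of the sum of squares of all entries."""
    return float(np.linalg.norm(as_array(T).ravel()))


@dataclass
class DifferenceOperator:
    """Stacked pairwise-difference map for one mode's similarity graph.

    For each edge ``l = (i, j)`` with ``i < j`` in the mode-``d`` edge set, the
    block ``A_{d,l} u`` is the vectorized difference of the i-th and j-th
    mode-d subarrays, i.e. row ``i`` minus row ``j`` of the mode-d
    matricization (the +1 lands on the smaller index).  The full operator maps
    R^n -> R^{|E_d| * n_{-d}}, realized matrix-free through matricization:
    a dense Kronecker representation is never formed, so applying the map and
    its adjoint costs O(|E_d| * n / n_d).
    """

    shape: tuple[int, ...]
    d: int  # 1-based mode
    edges: np.ndarray = field(repr=False)  # (|E_d|, 2) 0-based, i < j
    _phi: object = field(default=None, repr=False, compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def incidence(self):
        """Sparse |E_d| x n_d oriented incidence matrix Phi_d (+1 on the
        smaller endpoint, -1 on the larger), built lazily and cached."""
        if self._phi is None:
            from scipy.sparse import csr_matrix

            m = len(self.edges)
            data = np.tile([1.0, -1.0], m)
            rows = np.repeat(np.arange(m), 2)
            cols = self.edges.ravel()
            object.__setattr__(self, "_phi", csr_matrix(
                (data, (rows, cols)), shape=(m, self.n_d)
            ))
        return self._phi

    @property
    def n_d(self) -> int:
        return self.shape[self.d - 1]

    @property
    def n_minus_d(self) -> int:
        nd = self.n_d
        return int(np.prod(self.shape)) // nd

    def apply(self, u: np.ndarray) -> np.ndarray:
        """Map vec(U) to the (|E_d|, n_{-d}) array of edge-difference blocks."""
        M = matricize(unvectorize(u, self.shape), self.d)
        return self.incidence @ M

    def apply_transpose(self, V: np.ndarray) -> np.ndarray:
        """Adjoint map: (|E_d|, n_{-d}) edge blocks back to a vector in R^n."""
        M = self.incidence.T @ np.asarray(V)
        return vectorize(dematricize(M, self.shape, self.d))


def build_difference_operator(
    shape: tuple[int, ...], d: int, edges
) -> DifferenceOperator:
    """Validate a 1-based edge list ``[(i, j), ...]`` and build the operator."""
    shape = tuple(int(s) for s in shape)
    ax = _check_mode(d, len(shape))
    nd = shape[ax]
    E = np.asarray(list(edges), dtype=int)
    if E.size == 0:
        E = E.reshape(0, 2)
    if E.ndim != 2 or E.shape[1] != 2:
        raise ValueError("edges must be a sequence of (i, j) pairs")
    if np.any(E[:, 0] >= E[:, 1]):
        raise ValueError("each edge must satisfy i < j")
    if np.any(E < 1) or np.any(E > nd):
        raise ValueError(f"edge endpoints must lie in 1..{nd}")
    keys = {tuple(e) for e in E}
    if len(keys) != len(E):
        raise ValueError("duplicate edges are not allowed")
    return DifferenceOperator(shape=shape, d=d, edges=E - 1)
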