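"""Comparison methods: CPD+k-means and per-mode k-means (CoTeC style).

CPD+k-means performs a rank-R CP decomposition (alternating least squares,
multi-start best fit) and then clusters the rows of each factor matrix
independently with k-means.  CoTeC clusters the rows of each mode's
matricization directly, ignoring the multiway structure.  When k is not
given, it is chosen per mode by the gap statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .partitions import adjusted_rand_index
from .tensor_core import as_array, frobenius_norm, matricize

__all__ = [
    "BaselineResult",
    "cp_als",
    "cpd_kmeans",
    "cotec_kmeans",
    "gap_statistic",
]


@dataclass
class BaselineResult:
    """Per-mode labels from a baseline method, plus the choices it made."""

    method: str
    labels: list[np.ndarray]
    k_values: tuple[int, ...]
    rank: int | None = None
    ari: tuple[float, ...] | None = None
    meta: dict = field(default_factory=dict)

    def score_against(self, truth: list[np.ndarray]) -> "BaselineResult":
        self.ari = tuple(
            adjusted_rand_index(lab, t) for lab, t in zip(self.labels, truth)
        )
        return self


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    """Column-wise Khatri-Rao product, columns ordered to match the canonical
    unfolding (first matrix varies fastest)."""
    out = mats[0]
    for M in mats[1:]:
        out = np.einsum("ir,jr->jir", out, M).reshape(-1, out.shape[1])
    return out


def cp_als(
    X,
    R: int,
    seed: int = 0,
    n_starts: int = 3,
    n_iter: int = 200,
    tol: float = 1e-7,
):
    """Rank-R CP decomposition by alternating least squares.

    Runs ``n_starts`` seeded random initializations and keeps the best fit.
    Returns ``(factors, rel_error)`` with ``factors[d]`` of shape (n_d, R);
    component weights are absorbed into the last factor.
    """
    arr = as_array(X)
    D = arr.ndim
    if not 1 <= R <= min(arr.size // s for s in arr.shape):
        raise ValueError(f"infeasible CP rank {R} for shape {arr.shape}")
    xnorm = max(frobenius_norm(arr), 1e-300)
    unfoldings = [matricize(arr, d + 1) for d in range(D)]
    rng = np.random.default_rng(seed)
    best = (np.inf, None)
    for _ in range(n_starts):
        factors = [rng.standard_normal((s, R)) for s in arr.shape]
        grams = [F.T @ F for F in factors]
        prev = np.inf
        for _ in range(n_iter):
            for d in range(D):
                others = [factors[j] for j in range(D) if j != d]
                V = np.ones((R, R))
                for j in range(D):
                    if j != d:
                        V *= grams[j]
                K = _khatri_rao(others)
                factors[d] = np.linalg.lstsq(V.T, (unfoldings[d] @ K).T, rcond=None)[0].T
                grams[d] = factors[d].T @ factors[d]
            approx = factors[-1] @ _khatri_rao(factors[:-1]).T
            err = float(np.linalg.norm(unfoldings[-1] - approx)) / xnorm
            if abs(prev - err) <= tol:
                break
            prev = err
        if err < best[0]:
            best = (err, [F.copy() for F in factors])
    return best[1], best[0]


def _kmeans_labels(rows: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31))
    return km.fit_predict(rows) + 1


def _within_dispersion(rows: np.ndarray, k: int, seed: int) -> float:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31)).fit(rows)
    return float(km.inertia_) if k > 1 else float(
        np.sum((rows - rows.mean(axis=0)) ** 2)
    )


def gap_statistic(
    rows: np.ndarray,
    k_candidates,
    B: int = 10,
    seed: int = 0,
) -> int:
    """Tibshirani gap statistic over a candidate list of cluster counts.

    Compares log within-cluster dispersion with its expectation under B
    uniform reference draws over the feature bounding box; selects the
    smallest k with gap(k) >= gap(k+1) - s_{k+1}.  Constant features
    (zero dispersion everywhere) return 1.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ks = sorted(int(k) for k in k_candidates)
    if not ks:
        raise ValueError("no candidate k values")
    if len(ks) == 1:
        return ks[0]
    if float(np.ptp(rows, axis=0).max(initial=0.0)) == 0.0:
        return 1
    rng = np.random.default_rng(seed)
    lo, hi = rows.min(axis=0), rows.max(axis=0)
    log_w = np.array(
        [np.log(max(_within_dispersion(rows, k, seed), 1e-300)) for k in ks]
    )
    ref = np.empty((B, len(ks)))
    for b in range(B):
        fake = rng.uniform(lo, hi, size=rows.shape)
        s = int(rng.integers(2**31))
        ref[b] = [np.log(max(_within_dispersion(fake, k, s), 1e-300)) for k in ks]
    gap = ref.mean(axis=0) - log_w
    sk = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            return ks[i]
    return ks[-1]


def _resolve_k(rows, k, nd, seed) -> int:
    if k == "auto":
        return gap_statistic(rows, range(1, min(nd, 10) + 1), seed=seed)
    k = int(k)
    if not 1 <= k <= nd:
        raise ValueError(f"k={k} out of range for mode length {nd}")
    return k


def cpd_kmeans(X, R: int | str = "auto", k="auto", seed: int = 0) -> BaselineResult:
    """CP decomposition followed by per-mode k-means on the factor rows.

    ``R="auto"`` picks the rank in {2, 3, 4, 5} with the best relative fit
    improvement per component (elbow on the ALS fit); k is per-mode, either
    explicit, a list, or "auto" for gap-statistic selection.
    """
    arr = as_array(X)
    D = arr.ndim
    if R == "auto":
        cands = [r for r in (2, 3, 4, 5) if r <= min(arr.size // s for s in arr.shape)]
        errs = {r: cp_als(arr, r, seed=seed)[1] for r in cands}
        R = min(errs, key=lambda r: (round(errs[r], 4), r))
    factors, err = cp_als(arr, int(R), seed=seed)
    ks = list(k) if isinstance(k, (list, tuple)) else [k] * D
    labels, chosen = [], []
    for d in range(D):
        kd = _resolve_k(factors[d], ks[d], arr.shape[d], seed + d)
        labels.append(
            _kmeans_labels(factors[d], kd, seed + d) if kd > 1
            else np.ones(arr.shape[d], dtype=int)
        )
        chosen.append(kd)
    return BaselineResult(
        method="cpd+kmeans", labels=labels, k_values=tuple(chosen),
        rank=int(R), meta={"cp_rel_error": err},
    )


def cotec_kmeans(X, k="auto", seed: int = 0) -> BaselineResult:
    """k-means directly on the rows of each mode's matricization."""
    arr = as_array(X)
    D = arr.ndim
    ks = list(k) if isinstance(k, (list, tuple)) else [k] * D
    labels, chosen = [], []
    for d in range(D):
        rows = matricize(arr, d + 1)
        kd = _resolve_k(rows, ks[d], arr.shape[d], seed + d)
        labels.append(
            _kmeans_labels(rows, kd, seed + d) if kd > 1
            else np.ones(arr.shape[d], dtype=int)
        )
        chosen.append(kd)
    return BaselineResult(method="cotec", labels=labels, k_values=tuple(chosen))
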