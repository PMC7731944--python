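"""Gamma grids, eBIC scoring along the solution path, and selection.

The extended BIC for a fit at penalty level gamma is

    eBIC(gamma) = n * log(RSS_gamma / n) + 2 * df_gamma * log(n),

with RSS the residual sum of squares ||x - u_hat||^2, df the number of
co-clusters (each cell mean is one estimated parameter), and n the total
number of tensor entries.  The selected gamma minimizes the eBIC over the
grid, ties broken toward the smaller gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dual_solver import CoCoFit, SolverConfig, find_gamma_max, solution_path
from .mode_graphs import ModeGraph
from .partitions import CoClustering, count_co_clusters, extract_partitions
from .tensor_core import vectorize

__all__ = [
    "PathSelection",
    "ebic",
    "select_gamma",
    "default_gamma_grid",
    "theory_gamma_bounds",
    "fit_path",
]

RSS_FLOOR_REL = 1e-12  # floor on RSS relative to ||x||^2, guards log(0)


@dataclass
class PathSelection:
    """Scored solution path: per-gamma RSS, df, eBIC, cluster counts and the
    index of the eBIC-minimizing fit."""

    gammas: np.ndarray
    rss: np.ndarray
    df: np.ndarray
    ebic_values: np.ndarray
    cluster_counts: list[tuple[int, ...]]
    selected_index: int
    fits: list[CoCoFit] = field(repr=False)
    clusterings: list[CoClustering] = field(repr=False)
    rss_floored: np.ndarray = None

    @property
    def selected_gamma(self) -> float:
        return float(self.gammas[self.selected_index])

    @property
    def selected_fit(self) -> CoCoFit:
        return self.fits[self.selected_index]

    @property
    def selected_clustering(self) -> CoClustering:
        return self.clusterings[self.selected_index]


def ebic(x, u, df: int) -> float:
    """Extended BIC of an estimate ``u`` for data ``x`` with ``df`` estimated
    co-cluster means; RSS is floored at 1e-12 * ||x||^2 so an exact fit stays
    finite."""
    if df < 1:
        raise ValueError("df must be >= 1")
    xv = vectorize(x)
    uv = np.asarray(u, dtype=float).ravel()
    n = xv.size
    rss = float(np.sum((xv - uv) ** 2))
    floor = RSS_FLOOR_REL * float(np.sum(xv**2))
    return n * np.log(max(rss, floor) / n) + 2.0 * df * np.log(n)


def select_gamma(gammas, ebic_values) -> int:
    """Index of the eBIC-minimizing gamma; ties go to the smaller gamma."""
    g = np.asarray(gammas, dtype=float)
    e = np.asarray(ebic_values, dtype=float)
    if g.size == 0:
        raise ValueError("empty path")
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite eBIC values in path")
    # argmin returns the first minimizer; grid is ascending, so ties resolve
    # to the smaller gamma
    order = np.argsort(g, kind="stable")
    best = order[int(np.argmin(e[order]))]
    return int(best)


def theory_gamma_bounds(n: int, D: int, c0: float = 2.0) -> tuple[float, float]:
    """Endpoints 2*log(n)/(n*D) and 2*c0*log(n)/(n*D) of the tuning range
    under which the prediction-error bound is stated (c0 > 1)."""
    if c0 <= 1:
        raise ValueError("c0 must exceed 1")
    lo = 2.0 * np.log(n) / (n * D)
    return lo, c0 * lo


def default_gamma_grid(
    x,
    graph: ModeGraph,
    size: int = 30,
    config: SolverConfig | None = None,
    gamma_max: float | None = None,
    min_frac: float = 1e-6,
) -> np.ndarray:
    """Geometric grid from ``min_frac * gamma_max`` to ``gamma_max``, with
    gamma_max discovered by doubling until full fusion; gamma = 0 is excluded
    (the exact-fit end is degenerate for the eBIC).

    The span is wide because adaptive Gaussian-kernel weights make the
    full-fusion gamma orders of magnitude larger than the gamma at which the
    cluster structure appears: the between-cluster weights are exponentially
    small, so the informative part of the path sits far below gamma_max.
    """
    if size < 2:
        raise ValueError("grid size must be >= 2")
    if gamma_max is None:
        gamma_max = find_gamma_max(x, graph, config=config)
    return np.geomspace(min_frac * gamma_max, gamma_max, size)


def fit_path(
    x,
    graph: ModeGraph,
    gammas=None,
    config: SolverConfig | None = None,
    grid_size: int = 30,
    **extract_kwargs,
) -> PathSelection:
    """Fit the solution path, score each point by eBIC, and select gamma*."""
    if gammas is None:
        gammas = default_gamma_grid(x, graph, size=grid_size, config=config)
    gammas = np.asarray(sorted(float(g) for g in gammas))
    fits = solution_path(x, graph, gammas, config=config)
    xv = vectorize(x)
    n = xv.size
    floor = RSS_FLOOR_REL * float(np.sum(xv**2))
    rss, dfs, ebics, counts, clusterings, floored = [], [], [], [], [], []
    for fit in fits:
        clust = extract_partitions(fit, X=x, graph=graph, **extract_kwargs)
        r = float(np.sum((xv - fit.u) ** 2))
        df = count_co_clusters(clust.labels)
        rss.append(r)
        dfs.append(df)
        floored.append(r < floor)
        ebics.append(n * np.log(max(r, floor) / n) + 2.0 * df * np.log(n))
        counts.append(clust.cluster_counts)
        clusterings.append(clust)
    idx = select_gamma(gammas, ebics)
    return PathSelection(
        gammas=gammas,
        rss=np.asarray(rss),
        df=np.asarray(dfs, dtype=int),
        ebic_values=np.asarray(ebics),
        cluster_counts=counts,
        selected_index=idx,
        fits=fits,
        clusterings=clusterings,
        rss_floored=np.asarray(floored),
    )
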