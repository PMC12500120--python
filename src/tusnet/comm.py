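"""Representative structural matrices and network communication models.

From a cohort of structural connectomes this module builds the four
communication models used to explain stimulation effects:

- ``distance``: cohort-mean streamline length, normalized by its maximum;
- ``SPE`` (shortest-path efficiency): inverse of the minimal transmission
  cost on the graph with edge costs ``L = 1 / Mbar``;
- ``SI`` (search information): bits needed to bias a random walk onto the
  stored shortest path, ``SI_ij = -log2 prod T`` along the route with
  ``T`` the row-normalized transition matrix;
- ``CMY`` (communicability): matrix exponential of the strength-normalized
  weights, counting walks of every length with factorial damping.

Shortest-path ties are broken deterministically (lexicographically smallest
node sequence) so that search information is reproducible.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .exceptions import IsolatedNodeError

__all__ = [
    "CommModelSet",
    "representative_distance",
    "representative_weights",
    "cost_matrix",
    "shortest_paths",
    "spe",
    "search_information",
    "communicability",
    "model_vector",
    "mid_heterogeneity_target",
    "build_comm_models",
]


@dataclass
class CommModelSet:
    """All communication models derived from one connectome cohort."""

    distance: np.ndarray  # mean length / max, in [0, 1]
    weights: np.ndarray  # mean weights / max, in [0, 1]
    cost: np.ndarray  # L = 1 / weights, inf where absent
    spl: np.ndarray  # shortest-path cost Lambda*
    routes: list  # routes[i][j]: node tuple of the optimal path
    spe: np.ndarray
    si: np.ndarray  # bits
    cmy: np.ndarray
    strength: np.ndarray
    normalization: str = "as_printed"

    @property
    def n_unreachable(self) -> int:
        off = ~np.eye(self.spl.shape[0], dtype=bool)
        return int(np.isinf(self.spl[off]).sum())

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "distance": self.distance,
            "spe": self.spe,
            "si": self.si,
            "cmy": self.cmy,
        }


def _mean_normalized(matrices: list[np.ndarray], what: str) -> np.ndarray:
    if not matrices:
        raise ValueError("need at least one connectome")
    mean = np.mean(matrices, axis=0)
    peak = mean.max()
    if peak <= 0:
        raise ValueError(f"all-zero {what} matrices")
    return mean / peak


def representative_distance(cohort) -> np.ndarray:
    """Cohort-mean streamline length divided by its maximum (max entry 1)."""
    return _mean_normalized([c.lengths for c in cohort], "length")


def representative_weights(cohort) -> np.ndarray:
    """Cohort-mean structural weights divided by the maximum, in [0, 1]."""
    return _mean_normalized([c.weights for c in cohort], "weight")


def cost_matrix(weights: np.ndarray) -> np.ndarray:
    """Communication cost ``L_ij = 1 / w_ij``; infinite where no edge."""
    w = np.asarray(weights, float)
    with np.errstate(divide="ignore"):
        L = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def shortest_paths(L: np.ndarray) -> tuple[np.ndarray, list]:
    """All-pairs minimal transmission cost and one optimal route per pair.

    Dijkstra from every source; when two paths tie in cost the
    lexicographically smallest node sequence wins, making the stored route
    (and hence search information) deterministic.

    Returns
    -------
    spl : ndarray
        ``Lambda*``, with ``inf`` for unreachable pairs and 0 on the
        diagonal.
    routes : list of lists
        ``routes[i][j]`` is the node tuple ``(i, ..., j)`` or ``None``.
    """
    L = np.asarray(L, float)
    n = L.shape[0]
    nbrs = [np.where(np.isfinite(L[i]) & (np.arange(n) != i))[0] for i in range(n)]
    spl = np.full((n, n), np.inf)
    routes: list[list] = [[None] * n for _ in range(n)]
    for src in range(n):
        dist = np.full(n, np.inf)
        best: list = [None] * n
        dist[src] = 0.0
        best[src] = (src,)
        heap = [(0.0, (src,))]
        while heap:
            d, path = heapq.heappop(heap)
            u = path[-1]
            if d > dist[u] or path != best[u]:
                continue
            for v in nbrs[u]:
                nd = d + L[u, v]
                cand = path + (int(v),)
                if nd < dist[v] or (nd == dist[v] and (best[v] is None or cand < best[v])):
                    dist[v] = nd
                    best[v] = cand
                    heapq.heappush(heap, (nd, cand))
        spl[src] = dist
        routes[src] = best
    return spl, routes


def spe(spl: np.ndarray) -> np.ndarray:
    """Shortest-path efficiency ``1 / Lambda*``; 0 if unreachable, NaN diagonal."""
    spl = np.asarray(spl, float)
    with np.errstate(divide="ignore"):
        eff = np.where(np.isinf(spl), 0.0, 1.0 / np.where(spl > 0, spl, 1.0))
    np.fill_diagonal(eff, np.nan)
    return eff


def search_information(weights: np.ndarray, routes: list) -> np.ndarray:
    """Bits to bias a random walk onto the stored shortest path.

    The walk follows the row-normalized transition matrix
    ``T_ij = w_ij / sum_k w_ik``; the probability of taking the stored route
    is the product of ``T`` over its steps and ``SI = -log2`` of it.
    Asymmetric by construction.  ``inf`` marks unreachable pairs, the
    diagonal is NaN.
    """
    w = np.asarray(weights, float)
    n = w.shape[0]
    s = w.sum(axis=1)
    dead = np.where(s == 0)[0]
    if dead.size:
        raise IsolatedNodeError(f"zero-strength nodes: {dead.tolist()}")
    T = w / s[:, None]
    si = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            route = routes[i][j]
            if route is None:
                continue
            steps = T[route[:-1], route[1:]]
            with np.errstate(divide="ignore"):
                si[i, j] = -np.log2(steps).sum()
    np.fill_diagonal(si, np.nan)
    return si


def communicability(
    weights: np.ndarray, normalization: str = "as_printed"
) -> np.ndarray:
    """Matrix-exponential communicability of strength-normalized weights.

    ``CMY = exp(W')`` with ``W'_ij = w_ij / (s_i s_j)`` (``as_printed``) or
    the conventional ``w_ij / sqrt(s_i s_j)`` (``symmetric_sqrt``), where
    ``s`` is the row strength of the input.
    """
    w = np.asarray(weights, float)
    s = w.sum(axis=1)
    dead = np.where(s == 0)[0]
    if dead.size:
        raise IsolatedNodeError(f"zero-strength nodes: {dead.tolist()}")
    if normalization == "as_printed":
        wp = w / np.outer(s, s)
    elif normalization == "symmetric_sqrt":
        wp = w / np.sqrt(np.outer(s, s))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return expm(wp)


def model_vector(
    model: np.ndarray, mode: str, target: int | None = None
) -> np.ndarray:
    """Collapse a model matrix to a per-region vector.

    ``seed_row`` returns the row at the stimulation target (how the model
    sees propagation from the stimulated site); ``node_summary`` returns the
    per-region row median excluding the diagonal, min-max scaled to [0, 1]
    (the heterogeneity vector fed to the whole-brain model).
    """
    m = np.asarray(model, float)
    n = m.shape[0]
    if mode == "seed_row":
        if target is None or not 0 <= target < n:
            raise ValueError(f"seed_row needs a target in 0..{n - 1}")
        return m[target].copy()
    if mode != "node_summary":
        raise ValueError(f"unknown mode {mode!r}")
    masked = m.astype(float).copy()
    np.fill_diagonal(masked, np.nan)
    med = np.nanmedian(masked, axis=1)
    lo, hi = np.min(med), np.max(med)
    if hi == lo:
        warnings.warn(
            "constant node summary; returning all zeros", RuntimeWarning, stacklevel=2
        )
        return np.zeros(n)
    return (med - lo) / (hi - lo)


def mid_heterogeneity_target(beta) -> int:
    """Index of the region whose heterogeneity is closest to 0.5.

    The canonical stimulation site for simulated perturbation protocols: a
    mid-heterogeneity region sits near the oscillators' bifurcation under
    the control calibration, so sweeping the stimulation intensity from
    negative to positive actually carries it from the noise-dominated to
    the limit-cycle regime.  Ties break to the lowest index.
    """
    beta = np.asarray(beta, float)
    return int(np.argmin(np.abs(beta - 0.5)))


def build_comm_models(cohort, normalization: str = "as_printed") -> CommModelSet:
    """Compute every communication model for a connectome cohort."""
    dist = representative_distance(cohort)
    w = representative_weights(cohort)
    L = cost_matrix(w)
    spl, routes = shortest_paths(L)
    return CommModelSet(
        distance=dist,
        weights=w,
        cost=L,
        spl=spl,
        routes=routes,
        spe=spe(spl),
        si=search_information(w, routes),
        cmy=communicability(w, normalization),
        strength=w.sum(axis=1),
        normalization=normalization,
    )
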