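"""Metric cell-state space and density-adaptive k*-NN network.

Each cell's normalized multilevel encoding is treated as a probability
distribution over archetypes; the distance between two cells is the square
root of the Jensen–Shannon divergence with base-2 logarithms, which is a
proper metric bounded in [0, 1]. The cell network keeps, for every cell, a
locally chosen number of neighbors (the k* rule reads the neighbor count off
the local distance distribution), converts kept distances into smoothed
affinities with a per-cell bandwidth, and symmetrizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CellNetwork",
    "normalize_encodings",
    "jsd_distance",
    "jsd_to_many",
    "kstar_neighbors",
    "smooth_weights",
    "build_network",
]


@dataclass
class CellNetwork:
    nodes: list[str]
    weights: sp.csr_matrix  # symmetric smoothed affinities in (0, 1]
    distances: sp.csr_matrix  # raw metric distances on kept edges
    kappa: float
    neighbor_counts: np.ndarray  # per-cell n_opt before symmetrization

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return self.weights.nnz // 2

    def igraph(self):
        """The network as an undirected weighted igraph graph."""
        import igraph as ig

        coo = sp.triu(self.weights, k=1).tocoo()
        g = ig.Graph(
            n=self.n_cells,
            edges=list(zip(coo.row.tolist(), coo.col.tolist())),
            edge_attrs={"weight": coo.data.tolist()},
        )
        return g


def normalize_encodings(H_star: np.ndarray) -> np.ndarray:
    """Rescale each column of ``H*`` to sum 1 (a distribution over patterns).

    Since every one of the L level blocks of ``H*`` is already column
    stochastic, the result equals ``H_star / L`` exactly; the general
    column-sum division is used so partially assembled inputs also work.
    """
    H_star = np.asarray(H_star, dtype=float)
    if np.any(H_star < -1e-12):
        raise ValueError("H_star must be non-negative")
    sums = H_star.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("H_star has zero columns; cannot normalize")
    return H_star / sums


def jsd_distance(h_i: np.ndarray, h_j: np.ndarray) -> float:
    """Square root of the base-2 Jensen–Shannon divergence between two
    distributions; a metric with values in [0, 1]."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    if h_i.shape != h_j.shape:
        raise ValueError("length mismatch")
    if np.any(h_i < 0) or np.any(h_j < 0):
        raise ValueError("negative entries are not probabilities")
    return float(jsd_to_many(h_i, h_j[:, None])[0])


def jsd_to_many(h: np.ndarray, H: np.ndarray) -> np.ndarray:
    """sqrt-JSD (base 2) between vector ``h`` and each column of ``H``.

    Uses the entropy form JS(p||q) = H((p+q)/2) - (H(p)+H(q))/2 with the
    0*log 0 = 0 convention; clips tiny negative round-off before the sqrt.
    """
    h = np.asarray(h, dtype=float)
    H = np.asarray(H, dtype=float)
    M = 0.5 * (H + h[:, None])
    js = _entropy_cols(M) - 0.5 * (_entropy_cols(H) + _entropy_cols(h[:, None]))
    return np.sqrt(np.clip(js, 0.0, 1.0))


def _entropy_cols(P: np.ndarray) -> np.ndarray:
    logP = np.zeros_like(P)
    np.log2(P, out=logP, where=P > 0)
    return -(P * logP).sum(axis=0)


def kstar_neighbors(beta: np.ndarray) -> int:
    """Adaptive neighbor count from an ascending candidate-distance list.

    Runs the k*-NN selection loop: lambda_1 = beta_1 + 1, then for
    n = 1..N-1 break as soon as lambda_n <= beta_n, otherwise accumulate
    running sums and set
    lambda_{n+1} = (Sum_beta + sqrt(n + Sum_beta^2 - n * Sum_beta_sq)) / n.
    Returns the break index, or N-1 when the loop never breaks (equidistant
    neighbors never trigger the break).
    """
    beta = np.asarray(beta, dtype=float)
    N = beta.size
    if N == 0:
        raise ValueError("empty distance vector")
    if N == 1:
        return 1
    sum_b = 0.0
    sum_b2 = 0.0
    lam = beta[0] + 1.0
    for n in range(1, N):
        b = beta[n - 1]
        if lam <= b:
            return n
        sum_b += b
        sum_b2 += b * b
        disc = n + sum_b * sum_b - n * sum_b2
        lam = (sum_b + np.sqrt(max(disc, 0.0))) / n
    return N - 1


def smooth_weights(delta_row: np.ndarray, tol: float = 1e-5) -> np.ndarray:
    """Convert an ascending row of kept-neighbor distances into affinities.

    ``w_j = exp(-(delta_j - rho) / sigma)`` with ``rho`` the closest distance
    and ``sigma`` solved by bisection so the weights sum to ``log2(k)``. For
    ``k = 1`` the single weight is 1 by convention (the log2(1) = 0 target is
    unattainable since the closest neighbor always has weight 1).
    """
    d = np.asarray(delta_row, dtype=float)
    k = d.size
    if k == 0:
        raise ValueError("empty distance row")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be ascending")
    if k == 1:
        return np.ones(1)
    rho = d[0]
    shifted = d - rho
    target = np.log2(k)
    span = shifted[-1]
    if span <= 0:  # all neighbors tied with the closest: weights saturate at 1
        return np.ones(k)

    def total(sigma: float) -> float:
        return float(np.exp(-shifted / sigma).sum())

    lo, hi = 1e-10, 10.0 * span
    # total() is increasing in sigma; expand hi if needed
    for _ in range(64):
        if total(hi) >= target:
            break
        hi *= 2
    if total(lo) >= target:
        sigma = lo
    else:
        sigma = 0.5 * (lo + hi)
        for _ in range(64):
            t = total(sigma)
            if abs(t - target) < 0.1 * tol:
                break
            if t < target:
                lo = sigma
            else:
                hi = sigma
            sigma = 0.5 * (lo + hi)
    return np.exp(-shifted / sigma)


def _candidate_budget(n: int) -> int:
    return min(n - 1, max(30, int(np.ceil(np.sqrt(n)))))


def build_network(
    H_star_norm: np.ndarray,
    kappa: float = 1.0,
    cell_names: list[str] | None = None,
    n_candidates: int | None = None,
    exact: bool = False,
) -> CellNetwork:
    """Build the density-adaptive cell network from normalized encodings.

    Candidate neighbors are retrieved with a Euclidean nearest-neighbor
    search on the square-rooted probability vectors (the Hellinger embedding,
    which orders pairs almost identically to the JSD metric), re-ranked with
    the exact sqrt-JSD distance, scaled by ``kappa`` and passed through the
    k* rule to pick each cell's neighbor count; kept distances are smoothed
    into affinities and the directed graph is symmetrized with
    ``max(w_ij, w_ji)``. ``exact=True`` skips the embedding shortcut and uses
    brute-force JSD candidates.
    """
    H = np.asarray(H_star_norm, dtype=float)
    T, n = H.shape
    if n < 2:
        raise ValueError("need at least 2 cells to build a network")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if cell_names is None:
        cell_names = [f"cell_{i}" for i in range(n)]
    m = n_candidates if n_candidates is not None else _candidate_budget(n)
    m = min(m, n - 1)

    if exact:
        cand = np.empty((n, m), dtype=int)
        for i in range(n):
            d = jsd_to_many(H[:, i], H)
            d[i] = np.inf
            cand[i] = np.argsort(d, kind="stable")[:m]
    else:
        emb = np.sqrt(H.T)
        nn = NearestNeighbors(n_neighbors=m + 1).fit(emb)
        _, idx = nn.kneighbors(emb)
        cand = np.empty((n, m), dtype=int)
        for i in range(n):
            row = idx[i][idx[i] != i][:m]
            if row.size < m:  # duplicates of self at distance 0
                extra = [j for j in range(n) if j != i and j not in row]
                row = np.concatenate([row, extra[: m - row.size]])
            cand[i] = row

    rows, cols, wvals, dvals = [], [], [], []
    n_opt_arr = np.empty(n, dtype=int)
    for i in range(n):
        d_exact = jsd_to_many(H[:, i], H[:, cand[i]])
        order = np.argsort(d_exact, kind="stable")
        d_sorted = d_exact[order]
        nbrs = cand[i][order]
        n_opt = kstar_neighbors(kappa * d_sorted)
        n_opt_arr[i] = n_opt
        keep_d = d_sorted[:n_opt]
        w = smooth_weights(keep_d)
        rows.extend([i] * n_opt)
        cols.extend(nbrs[:n_opt].tolist())
        wvals.extend(w.tolist())
        dvals.extend(keep_d.tolist())

    Wd = sp.csr_matrix((wvals, (rows, cols)), shape=(n, n))
    Dd = sp.csr_matrix((dvals, (rows, cols)), shape=(n, n))
    W = Wd.maximum(Wd.T)
    # keep the distance wherever an edge survived (distances are symmetric
    # by definition; take the max to fill one-sided entries)
    D = Dd.maximum(Dd.T)
    W.setdiag(0)
    W.eliminate_zeros()
    D.setdiag(0)
    D.eliminate_zeros()
    return CellNetwork(
        nodes=list(cell_names),
        weights=W.tocsr(),
        distances=D.tocsr(),
        kappa=float(kappa),
        neighbor_counts=n_opt_arr,
    )
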