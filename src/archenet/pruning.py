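"""Pruning the multilevel archetype set into multiresolution states.

Running the decomposition at every resolution rediscovers dominant patterns
many times over. Each pattern is characterized by its influential cells (the
support of its column of ``C*``); two patterns are equivalent when their
influential-cell sets overlap more than chance (hypergeometric tail). Leiden
clustering of the resulting pattern graph yields equivalence classes; each
class is represented by its lowest-resolution member, and the class size is
reported as a dominance score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from scipy.stats import hypergeom

from .decomposition import NONZERO_THRESHOLD
from .multilevel import MultilevelDecomposition

__all__ = [
    "MultiresolutionStates",
    "influential_cells",
    "overlap_significance",
    "prune",
]


@dataclass
class MultiresolutionStates:
    selected: list[tuple[int, int]]  # (level k, within-level index) per representative
    selected_flat: list[int]  # column indices into the multilevel matrices
    W_mr: np.ndarray  # D x m
    H_mr: np.ndarray  # m x cells
    C_mr: np.ndarray  # cells x m
    class_members: list[list[tuple[int, int]]]
    dominance: np.ndarray  # per-representative class size
    n_levels: int

    @property
    def n_states(self) -> int:
        return len(self.selected)


def influential_cells(
    C_column: np.ndarray, threshold: float = NONZERO_THRESHOLD
) -> np.ndarray:
    """Indices of cells with influence above the nonzero threshold."""
    return np.flatnonzero(np.asarray(C_column) > threshold)


def overlap_significance(set_a, set_b, n_cells: int) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    ``P(X >= |a & b|)`` when ``|a|`` cells are drawn without replacement from
    ``n_cells`` of which ``|b|`` are marked; symmetric in its arguments.
    Empty sets give p = 1 with a warning.
    """
    a = set(int(x) for x in set_a)
    b = set(int(x) for x in set_b)
    if not a or not b:
        warnings.warn("empty influential-cell set; overlap p-value set to 1")
        return 1.0
    if any(x < 0 or x >= n_cells for x in a | b):
        raise ValueError("cell indices out of range")
    overlap = len(a & b)
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(overlap - 1, n_cells, len(b), len(a)))


def prune(
    ml: MultilevelDecomposition,
    sig_threshold: float = 0.01,
    leiden_resolution: float = 8.0,
    seed: int = 0,
    threshold: float = NONZERO_THRESHOLD,
) -> MultiresolutionStates:
    """Collapse the multilevel pattern set to nonredundant representatives.

    Builds the pattern graph (nodes = all T patterns, edges where the
    influential-cell overlap p-value beats ``sig_threshold``, weighted by
    ``-log10 p`` capped at 300), clusters it with Leiden, and keeps per class
    the member found at the smallest k (ties: smallest within-level index).
    The representatives' columns/rows of ``W*``, ``H*``, ``C*`` form the
    multiresolution decomposition.
    """
    T = ml.T
    n_cells = ml.n_cells
    supports = np.asarray(ml.C_star > threshold)  # cells x T boolean
    sizes = supports.sum(axis=0)

    # vectorized pairwise hypergeometric upper tails
    overlap = supports.T.astype(np.int32) @ supports.astype(np.int32)
    iu, ju = np.triu_indices(T, k=1)
    with np.errstate(all="ignore"):
        pvals = hypergeom.sf(
            overlap[iu, ju] - 1, n_cells, sizes[ju], sizes[iu]
        )
    pvals = np.where((sizes[iu] == 0) | (sizes[ju] == 0), 1.0, pvals)
    keep = pvals < sig_threshold
    if not np.any(keep):
        warnings.warn(
            "no significant pattern overlaps; every pattern is its own class"
        )
    edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    wts = np.minimum(-np.log10(np.maximum(pvals[keep], 1e-300)), 300.0)

    g = ig.Graph(n=T, edges=edges, edge_attrs={"weight": wts.tolist()})
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=leiden_resolution,
        seed=seed,
        n_iterations=-1,
    )

    selected: list[tuple[int, int]] = []
    selected_flat: list[int] = []
    class_members: list[list[tuple[int, int]]] = []
    dominance: list[int] = []
    for community in sorted(part, key=min):
        members = sorted(ml.level_of[i] for i in community)
        rep = members[0]  # smallest k, then smallest within-level index
        flat = ml.level_of.index(rep)
        selected.append(rep)
        selected_flat.append(flat)
        class_members.append(members)
        dominance.append(len(members))

    idx = np.asarray(selected_flat, dtype=int)
    return MultiresolutionStates(
        selected=selected,
        selected_flat=selected_flat,
        W_mr=ml.W_star[:, idx].copy(),
        H_mr=ml.H_star[idx, :].copy(),
        C_mr=ml.C_star[:, idx].copy(),
        class_members=class_members,
        dominance=np.asarray(dominance),
        n_levels=len(ml.levels),
    )
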