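"""Network-based interpretation: diffusion, marker typing, label propagation,
state footprints and enrichment, and graph clustering.

All operations act on the cell network's smoothed affinities. Marker-based
typing diffuses each marker gene's expression over the network (personalized
propagation), scores each cell-type as the signed average of the diffused
positive/negative marker vectors, and converts scores to z-scores against a
null of random same-size gene draws. Partial labels are completed by a
label-propagation variant whose neighborhood evidence is tested against the
global label frequencies with a Chernoff-style binomial tail bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph  # noqa: F401  (re-exported backend for cluster_network)
import leidenalg
import numpy as np
import scipy.sparse as sp

from .kernel import ExpressionMatrix
from .network import CellNetwork
from .pruning import MultiresolutionStates

__all__ = [
    "MarkerSet",
    "CellAnnotation",
    "diffuse",
    "annotate_cells",
    "propagate_labels",
    "footprint",
    "state_enrichment",
    "cluster_network",
]


@dataclass
class MarkerSet:
    name: str
    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        dup = set(self.positive) & set(self.negative)
        if dup:
            raise ValueError(f"genes marked both + and - in {self.name!r}: {sorted(dup)}")
        if not self.positive and not self.negative:
            raise ValueError(f"marker set {self.name!r} is empty")


@dataclass
class CellAnnotation:
    labels: np.ndarray  # per-cell best label (object array of strings)
    zscores: np.ndarray  # cells x labels
    confidence: np.ndarray  # per-cell float
    label_names: list[str]


def _row_stochastic(W: sp.csr_matrix) -> sp.csr_matrix:
    deg = np.asarray(W.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sp.diags(1.0 / deg) @ W


def diffuse(
    net: CellNetwork,
    values: np.ndarray,
    alpha: float = 0.15,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Personalized-propagation smoothing of per-cell values.

    Fixed point of ``x = (1 - alpha) P x + alpha v`` with ``P`` the
    row-stochastic affinity matrix and ``alpha`` the restart probability,
    solved by power iteration. Accepts a vector or a cells x features matrix
    (diffusion is linear, so features are propagated jointly).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    v = np.asarray(values, dtype=float)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[:, None]
    if v.shape[0] != net.n_cells:
        raise ValueError("values length must equal the number of cells")
    P = _row_stochastic(net.weights)
    x = v.copy()
    for _ in range(max_iter):
        x_new = (1.0 - alpha) * (P @ x) + alpha * v
        err = np.abs(x_new - x).max()
        x = x_new
        if err < tol:
            return x[:, 0] if squeeze else x
    raise RuntimeError(f"diffusion did not converge within {max_iter} iterations "
                       f"(residual {err:.2e})")


def annotate_cells(
    expr: ExpressionMatrix,
    net: CellNetwork,
    markers: list[MarkerSet],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.15,
) -> CellAnnotation:
    """Marker-driven cell typing with permutation z-scores.

    Per marker set: score(cell) = mean(diffused positive markers) -
    mean(diffused negative markers). The null draws ``n_perm`` random gene
    panels of the same +/- sizes from all genes and recomputes the signed
    average; z = (score - null mean) / null sd per cell. Each cell gets the
    argmax-z label; confidence is the winning z.
    """
    rng = np.random.default_rng(seed)
    gene_idx = {g: i for i, g in enumerate(expr.gene_names)}
    X = expr.dense()  # genes x cells
    # diffuse every gene once; columns can then be averaged freely (linearity)
    imputed = diffuse(net, X.T, alpha=alpha)  # cells x genes
    n_genes = X.shape[0]

    kept: list[tuple[MarkerSet, np.ndarray, np.ndarray]] = []
    for ms in markers:
        pos = np.array([gene_idx[g] for g in ms.positive if g in gene_idx], dtype=int)
        neg = np.array([gene_idx[g] for g in ms.negative if g in gene_idx], dtype=int)
        missing = [g for g in ms.positive + ms.negative if g not in gene_idx]
        if missing:
            warnings.warn(f"marker set {ms.name!r}: dropping absent genes {missing}")
        if pos.size == 0 and neg.size == 0:
            warnings.warn(f"marker set {ms.name!r} has no genes in the matrix; skipped")
            continue
        kept.append((ms, pos, neg))
    if not kept:
        raise ValueError("no usable marker sets")

    n_cells = net.n_cells
    Z = np.zeros((n_cells, len(kept)))
    for col, (ms, pos, neg) in enumerate(kept):
        score = np.zeros(n_cells)
        if pos.size:
            score += imputed[:, pos].mean(axis=1)
        if neg.size:
            score -= imputed[:, neg].mean(axis=1)
        null = np.empty((n_perm, n_cells))
        for p in range(n_perm):
            draw = rng.choice(n_genes, size=pos.size + neg.size, replace=False)
            s = np.zeros(n_cells)
            if pos.size:
                s += imputed[:, draw[: pos.size]].mean(axis=1)
            if neg.size:
                s -= imputed[:, draw[pos.size:]].mean(axis=1)
            null[p] = s
        sd = null.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z[:, col] = (score - null.mean(axis=0)) / sd

    best = Z.argmax(axis=1)
    names = [ms.name for ms, _, _ in kept]
    labels = np.array([names[i] for i in best], dtype=object)
    return CellAnnotation(
        labels=labels,
        zscores=Z,
        confidence=Z[np.arange(n_cells), best],
        label_names=names,
    )


def _chernoff_log_pvalue(evidence: float, total: float, freq: float) -> float:
    """Natural-log upper bound on P(weighted evidence >= observed) under the
    null that neighbors are labeled by the global frequency ``freq``.

    Chernoff bound for the relative-entropy form: log p <= -total * KL(q||f)
    with q = evidence/total, monotone decreasing in evidence for q > f (zero
    otherwise, i.e. no significance without enrichment).
    """
    if total <= 0 or freq <= 0:
        return 0.0
    q = min(max(evidence / total, 0.0), 1.0)
    if q <= freq:
        return 0.0
    f = min(freq, 1 - 1e-12)
    kl = q * np.log(q / f)
    if q < 1.0:
        kl += (1 - q) * np.log((1 - q) / (1 - f))
    return float(-total * kl)


def propagate_labels(
    net: CellNetwork,
    labels: np.ndarray,
    ratio_threshold: float = 2.0,
    max_iter: int = 10,
) -> CellAnnotation:
    """Fill in / revise labels from network neighborhoods.

    Per iteration (synchronous over cells): the evidence for label L at cell
    i is the summed affinity of i's neighbors carrying L; its confidence is
    the -log Chernoff tail bound of that evidence against the global
    frequency of L. Unlabeled cells adopt the most confident label;
    a labeled cell switches only when the challenger's confidence exceeds
    ``ratio_threshold`` times its current label's confidence. Stops at a
    fixed point or after ``max_iter`` sweeps. ``None``/empty entries mark
    unlabeled cells; at least one cell must be labeled.
    """
    cur = np.array(
        [None if (x is None or x == "" or (isinstance(x, float) and np.isnan(x))) else str(x)
         for x in labels],
        dtype=object,
    )
    if all(x is None for x in cur):
        raise ValueError("at least one labeled cell is required")
    names = sorted({x for x in cur if x is not None})
    name_of = {n: i for i, n in enumerate(names)}
    W = net.weights.tocsr()
    n = net.n_cells
    totals = np.asarray(W.sum(axis=1)).ravel()

    conf = np.zeros((n, len(names)))
    for _ in range(max_iter):
        onehot = np.zeros((n, len(names)))
        labeled = np.array([x is not None for x in cur])
        for i in np.flatnonzero(labeled):
            onehot[i, name_of[cur[i]]] = 1.0
        freq = onehot.sum(axis=0)
        freq = freq / max(freq.sum(), 1.0)
        evidence = W @ onehot  # cells x labels, weighted neighbor votes
        conf = np.zeros_like(evidence)
        for li in range(len(names)):
            if freq[li] <= 0:
                continue
            for i in range(n):
                conf[i, li] = -_chernoff_log_pvalue(
                    evidence[i, li], totals[i], freq[li]
                )
        best = conf.argmax(axis=1)
        new = cur.copy()
        changed = False
        for i in range(n):
            bi = int(best[i])
            if cur[i] is None:
                # imputation: adopt the strongest-evidence label even when it
                # is not enriched over the global frequency (e.g. a graph
                # carrying a single label), preferring significance when any
                if conf[i, bi] <= 0:
                    ev = evidence[i]
                    if ev.max() <= 0:
                        continue
                    bi = int(ev.argmax())
                new[i] = names[bi]
                changed = True
                continue
            if conf[i, bi] <= 0:
                continue
            elif names[bi] != cur[i]:
                old_conf = conf[i, name_of[cur[i]]]
                if conf[i, bi] > ratio_threshold * max(old_conf, 1e-12):
                    new[i] = names[bi]
                    changed = True
        cur = new
        if not changed:
            break

    idx = np.array([name_of.get(x, -1) for x in cur])
    confidence = np.where(idx >= 0, conf[np.arange(n), np.maximum(idx, 0)], 0.0)
    return CellAnnotation(labels=cur, zscores=conf, confidence=confidence,
                         label_names=names)


def footprint(
    states: MultiresolutionStates,
    which: int,
    net: CellNetwork | None = None,
    alpha: float = 0.15,
    normalized: bool = False,
) -> np.ndarray:
    """Per-cell activity of one multiresolution state (a row of H_mr).

    With ``normalized=True`` the row is divided by the number of levels, so
    the per-cell sum over all selected states is at most 1. Passing a network
    smooths the footprint by diffusion for display on the layout.
    """
    if not 0 <= which < states.n_states:
        raise IndexError(f"state index {which} out of range [0, {states.n_states})")
    v = states.H_mr[which].astype(float).copy()
    if normalized:
        v /= states.n_levels
    if net is not None:
        v = diffuse(net, v, alpha=alpha)
    return v


def state_enrichment(
    states: MultiresolutionStates,
    cell_values,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """states x features permutation z-scores of encoding/measurement overlap.

    The observed statistic is ``H_mr @ values``; the null permutes the cell
    order ``n_perm`` times. Categorical input (strings / non-numeric) is
    one-hot encoded internally, one feature per category. Returns the z
    matrix and the feature names.
    """
    import pandas as pd

    vals = np.asarray(cell_values)
    if vals.ndim == 1 and not np.issubdtype(vals.dtype, np.number):
        dummies = pd.get_dummies(pd.Series(vals))
        features = [str(c) for c in dummies.columns]
        V = dummies.to_numpy(dtype=float)
    else:
        V = vals.astype(float)
        if V.ndim == 1:
            V = V[:, None]
        features = [f"feature_{j}" for j in range(V.shape[1])]
    if V.shape[0] != states.H_mr.shape[1]:
        raise ValueError("cell_values length must equal the number of cells")
    rng = np.random.default_rng(seed)
    H = states.H_mr
    obs = H @ V  # m x F
    null = np.empty((n_perm,) + obs.shape)
    for p in range(n_perm):
        null[p] = H @ V[rng.permutation(V.shape[0])]
    sd = null.std(axis=0, ddof=1)
    # a permutation-invariant statistic has zero spread up to last-bit BLAS
    # jitter; force those z-scores to exactly zero
    degenerate = sd <= 1e-10 * np.maximum(np.abs(null).max(axis=0), 1.0)
    sd[degenerate] = np.inf
    z = (obs - null.mean(axis=0)) / sd
    return z, features


def cluster_network(net: CellNetwork, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden communities of the weighted cell network (seeded)."""
    g = net.igraph()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership)
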