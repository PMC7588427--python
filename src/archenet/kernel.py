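"""Expression-kernel transform and randomized-SVD reduction.

The decomposition layers never see the raw genes x cells matrix. Instead the
matrix is passed through a gene-reweighting transform that damps ubiquitously
expressed genes and boosts cell-specific ones (so no highly-variable-gene
preselection is needed), and the transformed matrix ``Z`` is compressed to a
rank-``D`` profile ``S_r`` whose Gram matrix ``S_r.T @ S_r`` approximates the
expression kernel ``K = Z.T @ Z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

__all__ = [
    "ExpressionMatrix",
    "ReducedProfile",
    "action_kernel_transform",
    "reduce",
]


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix with row/column names.

    ``values`` may be dense or scipy-sparse. ``metadata`` records provenance,
    e.g. the transform chain applied by :func:`action_kernel_transform`.
    """

    values: object
    gene_names: list[str]
    cell_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_genes, n_cells = self.values.shape
        if len(self.gene_names) != n_genes:
            raise ValueError(
                f"gene_names length {len(self.gene_names)} != {n_genes} rows"
            )
        if len(self.cell_names) != n_cells:
            raise ValueError(
                f"cell_names length {len(self.cell_names)} != {n_cells} columns"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class ReducedProfile:
    """Rank-D reduced representation of the transformed expression matrix.

    ``S_r`` is D x cells and satisfies ``S_r.T @ S_r ~= Z.T @ Z`` at rank D.
    ``gene_loadings`` (genes x D) maps reduced-space vectors back to gene
    space: a reduced column ``w`` corresponds to the gene-space profile
    ``gene_loadings @ w`` (up to the discarded tail of the spectrum).
    """

    S_r: np.ndarray
    D: int
    singular_values: np.ndarray
    gene_loadings: np.ndarray
    cell_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError("reduced rank D must be >= 2")
        sv = np.asarray(self.singular_values, dtype=float)
        if np.any(sv < -1e-12) or np.any(np.diff(sv) > 1e-9 * max(1.0, sv[0])):
            raise ValueError("singular_values must be non-negative, non-increasing")

    @property
    def n_cells(self) -> int:
        return self.S_r.shape[1]


def action_kernel_transform(
    expr: ExpressionMatrix, z_limit: float = 10.0
) -> ExpressionMatrix:
    """Apply the gene-reweighting transform chain to a counts matrix.

    Chain (recorded in the output metadata so downstream code can verify it):

    1. library-size normalization: each cell scaled to the median library size;
    2. ``log1p``;
    3. per-gene z-scoring (center and scale across cells), winsorized at
       ``+/- z_limit``.

    Centering removes genes expressed uniformly everywhere; division by the
    per-gene standard deviation up-weights genes whose expression is specific
    to few cells. Genes with zero variance (including all-zero genes) are kept
    as zero rows so the gene axis is stable.

    Raises ``ValueError`` when any cell has zero total counts (listing the
    offending cells) or the input contains non-finite values.
    """
    X = expr.dense()
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")
    lib = X.sum(axis=0)
    empty = np.flatnonzero(lib == 0)
    if empty.size:
        names = [expr.cell_names[i] for i in empty[:10]]
        raise ValueError(
            f"{empty.size} cell(s) have zero total counts and cannot be "
            f"normalized: {names}{'...' if empty.size > 10 else ''}"
        )
    target = float(np.median(lib))
    Z = np.log1p(X * (target / lib))
    mu = Z.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, ddof=0, keepdims=True)
    nz = sd[:, 0] > 0
    Z -= mu
    Z[nz] /= sd[nz]
    Z[~nz] = 0.0
    np.clip(Z, -z_limit, z_limit, out=Z)
    meta = dict(expr.metadata)
    meta["transform_chain"] = (
        "median-library-size",
        "log1p",
        f"per-gene-zscore(winsorize={z_limit:g})",
    )
    return ExpressionMatrix(Z, list(expr.gene_names), list(expr.cell_names), meta)


def reduce(
    Z: ExpressionMatrix,
    D: int = 50,
    seed: int = 0,
    n_oversamples: int = 10,
    n_iter: int = 5,
) -> ReducedProfile:
    """Rank-D reduction of the transformed matrix via randomized SVD.

    With ``Z ~= U diag(s) Vt``, the reduced profile is
    ``S_r = diag(s) @ Vt`` (D x cells), so that
    ``S_r.T @ S_r = V diag(s^2) Vt`` is the best rank-D approximation of the
    kernel ``Z.T @ Z``. ``gene_loadings = U``. Deterministic given ``seed``.
    """
    n_genes, n_cells = Z.shape
    if not (2 <= D < min(n_genes, n_cells)):
        raise ValueError(
            f"D={D} must satisfy 2 <= D < min(genes, cells) = {min(n_genes, n_cells)}"
        )
    U, s, Vt = randomized_svd(
        Z.values if sp.issparse(Z.values) else np.asarray(Z.values, dtype=float),
        n_components=D,
        n_oversamples=n_oversamples,
        n_iter=n_iter,
        random_state=seed,
    )
    S_r = s[:, None] * Vt
    meta = dict(Z.metadata)
    meta.update(reduction=dict(D=D, seed=seed, n_oversamples=n_oversamples, n_iter=n_iter))
    return ReducedProfile(
        S_r=np.ascontiguousarray(S_r),
        D=D,
        singular_values=s.copy(),
        gene_loadings=np.ascontiguousarray(U),
        cell_names=list(Z.cell_names),
        metadata=meta,
    )
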