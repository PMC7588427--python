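"""Multilevel decomposition: independent ACTION runs across resolutions.

A single resolution ``k`` cannot capture both coarse cell types and
fine-grained subtypes, so the decomposition is run at every
``k = k_min .. k_max`` and the per-level factors are concatenated into the
multilevel matrices ``C*`` (cells x T), ``H*`` (T x cells) and ``W*``
(D x T), with ``T = sum(k_min..k_max)``. Levels are computed independently
(each level is deterministic), so the result does not depend on the order in
which levels are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import NONZERO_THRESHOLD, ArchetypeDecomposition, run_action
from .kernel import ReducedProfile

__all__ = ["MultilevelDecomposition", "run_multilevel", "saturation_curve"]


@dataclass
class MultilevelDecomposition:
    levels: list[ArchetypeDecomposition]
    C_star: np.ndarray  # cells x T
    H_star: np.ndarray  # T x cells
    W_star: np.ndarray  # D x T
    level_of: list[tuple[int, int]]  # per concatenated pattern: (k, index within level)
    T: int

    @property
    def k_min(self) -> int:
        return self.levels[0].k

    @property
    def k_max(self) -> int:
        return self.levels[-1].k

    @property
    def n_cells(self) -> int:
        return self.C_star.shape[0]


def run_multilevel(
    S_r: ReducedProfile | np.ndarray,
    k_min: int = 2,
    k_max: int = 30,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MultilevelDecomposition:
    """Run ACTION for every k in ``[k_min, k_max]`` and concatenate factors."""
    if not (2 <= k_min <= k_max):
        raise ValueError(f"need 2 <= k_min <= k_max, got [{k_min}, {k_max}]")
    levels = [
        run_action(S_r, k, max_iter=max_iter, tol=tol)
        for k in range(k_min, k_max + 1)
    ]
    level_of = [(lvl.k, j) for lvl in levels for j in range(lvl.k)]
    C_star = np.hstack([lvl.C for lvl in levels])
    H_star = np.vstack([lvl.H for lvl in levels])
    W_star = np.hstack([lvl.W for lvl in levels])
    T = sum(lvl.k for lvl in levels)
    assert T == k_max * (k_max + 1) // 2 - k_min * (k_min - 1) // 2
    return MultilevelDecomposition(
        levels=levels, C_star=C_star, H_star=H_star, W_star=W_star,
        level_of=level_of, T=T,
    )


def saturation_curve(
    ml: MultilevelDecomposition, threshold: float = NONZERO_THRESHOLD
) -> dict[int, int]:
    """Per-level count of nontrivial C columns (more than one nonzero).

    SPA initialization gives each column of C exactly one nonzero; a column
    that stays that way through refinement marks a surplus archetype. The
    number of nontrivial columns grows with k until the data's state count is
    exhausted and then plateaus, which is how an effective ``k_max`` is read
    off the curve.
    """
    out: dict[int, int] = {}
    for lvl in ml.levels:
        nnz = (lvl.C > threshold).sum(axis=0)
        out[lvl.k] = int((nnz > 1).sum())
    return out
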