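"""Single-level archetypal decomposition (SPA initialization + AA refinement).

Archetypal analysis factors the reduced profile as ``S_r ~= (S_r C) H`` with
every column of ``C`` (cells x k) and ``H`` (k x cells) constrained to the
probability simplex. Each archetype ``W[:, j] = S_r @ C[:, j]`` is therefore a
convex combination of observed cells, which is what makes the factors
directly interpretable. Because plain AA only converges locally, the solver
is seeded with the successive projection algorithm (SPA) — the separable-NMF
selection rule with a global-optimality guarantee under its noise model —
which makes the whole path deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .kernel import ReducedProfile

__all__ = [
    "ArchetypeDecomposition",
    "spa_select",
    "simplex_lstsq",
    "aa_refine",
    "run_action",
]

#: coefficients above this value count as "nonzero" for influence/saturation
NONZERO_THRESHOLD = 1e-5


@dataclass
class ArchetypeDecomposition:
    k: int
    C: np.ndarray  # cells x k, columns on the simplex
    H: np.ndarray  # k x cells, columns on the simplex
    W: np.ndarray  # D x k, W = S_r @ C
    selected_indices: list[int]
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, M in (("C", self.C), ("H", self.H)):
            if np.any(M < -1e-12):
                raise ValueError(f"{name} has negative entries")
            if np.max(np.abs(M.sum(axis=0) - 1.0)) > 1e-8:
                raise ValueError(f"columns of {name} must sum to 1 within 1e-8")
        if any(
            b > a + 1e-9 * max(1.0, a)
            for a, b in zip(self.objective_trace, self.objective_trace[1:])
        ):
            raise ValueError("objective_trace must be non-increasing")


def spa_select(S_r: ReducedProfile | np.ndarray, k: int) -> list[int]:
    """Successive projection algorithm over the columns of ``S_r``.

    Repeatedly picks the column with the largest residual Euclidean norm and
    projects all columns onto the orthogonal complement of the pick.
    Deterministic; ties broken toward the lowest index. Raises when the
    residual collapses (rank-deficient input) before ``k`` picks are made.
    """
    X = S_r.S_r if isinstance(S_r, ReducedProfile) else np.asarray(S_r, dtype=float)
    n = X.shape[1]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    R = X.astype(float, copy=True)
    scale = float(np.linalg.norm(X))
    picked: list[int] = []
    for _ in range(k):
        norms = np.einsum("ij,ij->j", R, R)
        j = int(np.argmax(norms))  # argmax returns the lowest maximizing index
        if norms[j] <= max(scale, 1.0) ** 2 * 1e-24:
            raise ValueError(
                f"rank-deficient input: residual vanished after picking {picked}"
            )
        picked.append(j)
        u = R[:, j] / np.linalg.norm(R[:, j])
        R -= np.outer(u, u @ R)
    return picked


def simplex_lstsq(A: np.ndarray, B: np.ndarray, penalty: float | None = None) -> np.ndarray:
    """Column-wise least squares ``min ||A X - B||_F`` with simplex columns.

    Each column of ``X`` is non-negative and sums to one. Solved per column by
    Lawson–Hanson NNLS on the penalty-augmented system (an extra row enforcing
    the sum-to-one constraint with a large weight), then renormalized so the
    constraint holds exactly.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    m, p = A.shape
    if penalty is None:
        penalty = 1e3 * max(1.0, float(np.abs(A).max()))
    Aaug = np.vstack([A, np.full((1, p), penalty)])
    baug = np.empty(m + 1)
    X = np.empty((p, B.shape[1]))
    for j in range(B.shape[1]):
        baug[:m] = B[:, j]
        baug[m] = penalty
        x, _ = nnls(Aaug, baug)
        s = x.sum()
        X[:, j] = x / s if s > 0 else 1.0 / p
    return X


def _objective(S_r: np.ndarray, C: np.ndarray, H: np.ndarray) -> float:
    return float(np.linalg.norm(S_r - (S_r @ C) @ H, "fro") ** 2)


def aa_refine(
    S_r: ReducedProfile | np.ndarray,
    init_indices: list[int],
    k: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ArchetypeDecomposition:
    """Alternating simplex-constrained minimization of ``||S_r - S_r C H||_F``.

    ``C`` starts from one-hot columns at ``init_indices`` (the SPA picks). A
    sweep updates ``H`` given ``W = S_r C``, then each column of ``C`` given
    ``H``. Stops when the relative objective change drops below ``tol``, the
    sweep fails to improve, or ``max_iter`` sweeps elapse; the recorded
    objective trace is non-increasing by construction.
    """
    X = S_r.S_r if isinstance(S_r, ReducedProfile) else np.asarray(S_r, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("reduced profile contains non-finite values")
    n = X.shape[1]
    if k is None:
        k = len(init_indices)
    if k != len(init_indices):
        raise ValueError("k must equal len(init_indices)")
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    C = np.zeros((n, k))
    C[init_indices, np.arange(k)] = 1.0
    H = simplex_lstsq(X @ C, X)
    obj = _objective(X, C, H)
    trace = [obj]
    for _ in range(max_iter):
        C_new = _update_C(X, H, C)
        H_new = simplex_lstsq(X @ C_new, X)
        obj_new = _objective(X, C_new, H_new)
        if obj_new > obj * (1 + 1e-12):
            break  # numerically stalled; keep the best factors seen
        C, H = C_new, H_new
        improved = obj - obj_new
        trace.append(obj_new)
        if obj > 0 and improved / max(obj, 1e-300) < tol:
            obj = obj_new
            break
        obj = obj_new
    W = X @ C
    return ArchetypeDecomposition(
        k=k, C=C, H=H, W=W, selected_indices=list(init_indices), objective_trace=trace
    )


def _update_C(X: np.ndarray, H: np.ndarray, C_prev: np.ndarray) -> np.ndarray:
    """Cyclic block-coordinate update of C given H, warm-started at C_prev.

    With ``G = H H^T`` and ``F = X H^T``, the objective restricted to column
    ``j`` of C (others fixed) is a simplex-constrained least squares of
    ``X c_j`` against the residual target
    ``(F[:, j] - W G[:, j] + W[:, j] G[j, j]) / G[j, j]``. Every column update
    is an exact minimization, so the pass never increases the objective.
    Columns whose pattern carries no encoding mass (``G[j, j] ~ 0``) are left
    untouched; with SPA one-hot initialization this is what keeps surplus
    columns "trivial" once the data's state count is exhausted.
    """
    k = H.shape[0]
    C = C_prev.copy()
    G = H @ H.T
    F = X @ H.T
    W = X @ C
    for j in range(k):
        gjj = G[j, j]
        if gjj <= 1e-300:
            continue
        target = (F[:, j] - W @ G[:, j] + W[:, j] * gjj) / gjj
        C[:, j] = simplex_lstsq(X, target)[:, 0]
        W[:, j] = X @ C[:, j]
    return C


def run_action(S_r: ReducedProfile | np.ndarray, k: int, max_iter: int = 100,
               tol: float = 1e-6) -> ArchetypeDecomposition:
    """SPA selection followed by AA refinement; fully deterministic."""
    picks = spa_select(S_r, k)
    return aa_refine(S_r, picks, k=k, max_iter=max_iter, tol=tol)
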