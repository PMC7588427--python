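"""Network layout by stochastic gradient descent, and de novo coloring.

The cell network is embedded in 2 or 3 dimensions by minimizing the fuzzy
cross-entropy between the network's edge affinities and a smooth kernel
``f(d) = 1 / (1 + a d^(2b))`` over embedded distances — the UMAP objective,
driven here directly by the smoothed network weights. The ``(a, b)`` pair is
folded into a single 0–100 "compactness" knob. A 3D embedding is mapped into
the perceptually uniform CIELAB color space to give every cell a color that
reflects its position in the state landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.optimize import curve_fit
from scipy.sparse.linalg import eigsh

from .network import CellNetwork

__all__ = ["Embedding", "fit_ab", "compactness_to_spread", "embed", "denovo_colors"]


@dataclass
class Embedding:
    coords: np.ndarray  # cells x dims
    a: float
    b: float
    compactness: int
    seed: int

    @property
    def dims(self) -> int:
        return self.coords.shape[1]


def compactness_to_spread(compactness: int) -> float:
    """Map the 0–100 compactness knob to a min-dist-like spread value.

    Strictly decreasing: 0 -> 0.5 (loose), 100 -> 0.005 (tight), log-spaced.
    """
    if not 0 <= compactness <= 100:
        raise ValueError("compactness must be in [0, 100]")
    return float(0.5 * 10 ** (-2.0 * compactness / 100.0))


def fit_ab(compactness: int) -> tuple[float, float]:
    """Kernel parameters (a, b) for a given compactness.

    Least-squares fit of ``f(d) = 1/(1 + a d^(2b))`` to the smooth-step
    target (1 below ``min_dist``, exponential decay with unit spread above).
    """
    min_dist = compactness_to_spread(compactness)
    spread = 1.0
    xv = np.linspace(0, 3 * spread, 300)
    yv = np.where(xv < min_dist, 1.0, np.exp(-(xv - min_dist) / spread))

    def f(x, a, b):
        return 1.0 / (1.0 + a * x ** (2.0 * b))

    (a, b), _ = curve_fit(f, xv, yv, p0=(1.577, 0.895), maxfev=5000)
    return float(a), float(b)


@njit(cache=True)
def _sgd_layout(coords, heads, tails, epochs_per_sample, a, b, n_epochs,
                init_lr, neg_rate, rng_state):  # pragma: no cover - jit
    n_edges = heads.shape[0]
    n, dim = coords.shape
    next_sample = epochs_per_sample.copy()
    state = rng_state
    for epoch in range(n_epochs):
        lr = init_lr * (1.0 - epoch / n_epochs)
        for e in range(n_edges):
            if next_sample[e] > epoch:
                continue
            i = heads[e]
            j = tails[e]
            d2 = 0.0
            for c in range(dim):
                diff = coords[i, c] - coords[j, c]
                d2 += diff * diff
            if d2 > 0.0:
                coeff = -2.0 * a * b * d2 ** (b - 1.0) / (1.0 + a * d2**b)
            else:
                coeff = 0.0
            for c in range(dim):
                diff = coords[i, c] - coords[j, c]
                g = coeff * diff
                if g > 4.0:
                    g = 4.0
                elif g < -4.0:
                    g = -4.0
                coords[i, c] += lr * g
                coords[j, c] -= lr * g
            for _ in range(neg_rate):
                state = state * np.uint64(6364136223846793005) + np.uint64(
                    1442695040888963407
                )
                j2 = np.int64(state >> np.uint64(33)) % n
                if j2 == i:
                    continue
                d2 = 0.0
                for c in range(dim):
                    diff = coords[i, c] - coords[j2, c]
                    d2 += diff * diff
                if d2 > 0.0:
                    coeff = 2.0 * b / ((0.001 + d2) * (1.0 + a * d2**b))
                else:
                    coeff = 0.0
                for c in range(dim):
                    diff = coords[i, c] - coords[j2, c]
                    g = coeff * diff
                    if g > 4.0:
                        g = 4.0
                    elif g < -4.0:
                        g = -4.0
                    coords[i, c] += lr * g
            next_sample[e] += epochs_per_sample[e]
    return coords


def _spectral_init(W: sp.csr_matrix, dims: int, seed: int) -> np.ndarray:
    """Seeded spectral layout from the symmetric normalized Laplacian."""
    n = W.shape[0]
    deg = np.asarray(W.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    Dm = sp.diags(1.0 / np.sqrt(deg))
    L = sp.identity(n) - Dm @ W @ Dm
    rng = np.random.default_rng(seed)
    v0 = rng.normal(size=n)
    try:
        _, vecs = eigsh(L, k=dims + 1, sigma=0.0, which="LM", v0=v0)
        init = vecs[:, 1 : dims + 1]
    except Exception:
        init = rng.normal(size=(n, dims))
    init = init / max(np.abs(init).max(), 1e-12) * 10.0
    return np.ascontiguousarray(init + rng.normal(scale=1e-4, size=init.shape))


def embed(
    net: CellNetwork,
    dims: int = 2,
    compactness: int = 50,
    epochs: int = 500,
    seed: int = 0,
    neg_rate: int = 5,
    init_lr: float = 1.0,
) -> Embedding:
    """Lay the network out by per-edge stochastic gradient descent.

    Edges are sampled proportionally to their affinity (heavier edges pull
    more often per epoch); each attractive update is paired with ``neg_rate``
    sampled repulsive updates. Learning rate decays linearly. Deterministic
    for a fixed seed (single worker).
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if net.n_cells == 0 or net.weights.nnz == 0:
        raise ValueError("cannot embed an empty network")
    a, b = fit_ab(compactness)
    coo = sp.triu(net.weights, k=1).tocoo()
    w = coo.data.astype(np.float64)
    # UMAP-style schedule: the strongest edge is sampled every epoch
    eps = w.max() / w
    coords = _spectral_init(net.weights, dims, seed)
    coords = _sgd_layout(
        coords,
        coo.row.astype(np.int64),
        coo.col.astype(np.int64),
        eps.astype(np.float64),
        float(a),
        float(b),
        int(epochs),
        float(init_lr),
        int(neg_rate),
        np.uint64(seed * 2654435761 + 1),
    )
    return Embedding(coords=np.asarray(coords), a=a, b=b,
                     compactness=int(compactness), seed=int(seed))


def cross_entropy(net: CellNetwork, emb: Embedding, sample: int = 2000,
                  seed: int = 0) -> float:
    """Eq.-style layout objective estimated on a sample of edges.

    Sums ``w log(w/f(d)) + (1-w) log((1-w)/f(1-d))`` over up to ``sample``
    network edges; used to verify that optimization reduces the objective.
    """
    coo = sp.triu(net.weights, k=1).tocoo()
    rng = np.random.default_rng(seed)
    m = coo.nnz
    take = rng.choice(m, size=min(sample, m), replace=False)
    w = np.clip(coo.data[take], 1e-6, 1 - 1e-6)
    d = np.linalg.norm(emb.coords[coo.row[take]] - emb.coords[coo.col[take]], axis=1)

    def f(x):
        return 1.0 / (1.0 + emb.a * np.maximum(x, 1e-12) ** (2 * emb.b))

    fd = np.clip(f(d), 1e-6, 1 - 1e-6)
    f1d = np.clip(f(1.0 - np.clip(d, 0, 1)), 1e-6, 1 - 1e-6)
    return float(np.sum(w * np.log(w / fd) + (1 - w) * np.log((1 - w) / f1d)))


def denovo_colors(embedding3d: Embedding) -> np.ndarray:
    """Per-cell sRGB triplets derived from 3D coordinates via CIELAB.

    The highest-variance axis is mapped to lightness L* in [35, 85], the
    remaining axes to a*, b* in [-40, 40]; L*a*b* is converted to sRGB and
    clipped to [0, 1]. Coincident coordinates get identical colors; a fully
    degenerate (zero-variance) axis maps to the center of its channel range.
    """
    from skimage.color import lab2rgb

    if embedding3d.dims != 3:
        raise ValueError("de novo coloring needs a 3D embedding")
    X = np.asarray(embedding3d.coords, dtype=float)
    order = np.argsort(X.var(axis=0))[::-1]  # highest variance first -> L*
    lo = np.array([35.0, -40.0, -40.0])
    hi = np.array([85.0, 40.0, 40.0])
    lab = np.empty_like(X)
    for c, ax in enumerate(order):
        col = X[:, ax]
        span = col.max() - col.min()
        if span <= 0:
            lab[:, c] = 0.5 * (lo[c] + hi[c])
        else:
            lab[:, c] = lo[c] + (col - col.min()) / span * (hi[c] - lo[c])
    rgb = lab2rgb(lab[None, :, :])[0]
    return np.clip(rgb, 0.0, 1.0)
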