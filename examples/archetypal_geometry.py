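"""Archetype recovery on planted convex-hull geometry.

Builds a reduced profile whose first k cells are the vertices of a planted
simplex, with every other cell a convex mixture of them, then runs the
SPA-initialized archetypal decomposition and reports how well the learned
archetypes align with the planted vertices (cosine similarity; 1.0 means the
solver found the exact generating states).
"""

import numpy as np

from archenet import hull_fixture, run_action

profile, planted = hull_fixture(D=8, k=4, n_cells=120, seed=1)
dec = run_action(profile, k=4)

V = profile.S_r[:, planted]
cos = np.abs(
    (dec.W / np.linalg.norm(dec.W, axis=0)).T @ (V / np.linalg.norm(V, axis=0))
)
print(f"final reconstruction objective: {dec.objective_trace[-1]:.3e}")
print(f"solver sweeps: {len(dec.objective_trace)}")
for j, c in enumerate(cos.max(axis=0)):
    print(f"planted vertex {j}: best archetype cosine = {c:.6f}")
# cosines ~1 mean each planted extreme state was recovered as an archetype;
# the near-zero objective confirms the hull was reconstructed exactly.
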