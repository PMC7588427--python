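"""Multiresolution decomposition of the synthetic benchmark.

Generates one low-noise benchmark instance (13 identity programs defining
cell types plus 1 activity program shared as a gradient across half the
types), runs the kernel transform, rank-50 reduction and archetypal
decompositions at every k = 2..30, prunes the 464 concatenated patterns to
a nonredundant multiresolution state set, and scores how many planted
programs the states recover one-to-one.
"""

from archenet import (
    SyntheticConfig,
    action_kernel_transform,
    evaluate_recovery,
    generate,
    prune,
    reduce,
    run_multilevel,
    saturation_curve,
)

cfg = SyntheticConfig(seed=1, noise_level="low")
expr, truth = generate(cfg)
print(f"simulated {expr.shape[0]} genes x {expr.shape[1]} cells, "
      f"{truth.n_programs} planted programs")

red = reduce(action_kernel_transform(expr), D=50, seed=1)
ml = run_multilevel(red, k_min=2, k_max=30)
print(f"multilevel decomposition: T = {ml.T} patterns across "
      f"{len(ml.levels)} resolutions")

sat = saturation_curve(ml)
print("saturation (nontrivial patterns) at k = 5, 13, 20, 30:",
      [sat[k] for k in (5, 13, 20, 30)])
# the curve tracks k up to the planted program count, then flattens: extra
# resolution stops discovering genuinely new patterns.

states = prune(ml, seed=1)
print(f"pruning: {ml.T} patterns -> {states.n_states} multiresolution states")

report = evaluate_recovery(states, truth, gene_loadings=red.gene_loadings)
print(f"programs matched one-to-one: {report['n_matched']} / "
      f"{report['n_programs']}")
for e in report["matches"][:3]:
    print(f"  program {e['program']} -> state {e['state']} "
          f"(capture -log10 p = {e['score']:.1f})")
# a capture score of s means the state's encoding separates the program's
# cells from the rest with Welch-t p = 10^-s.
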