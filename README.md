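# archenet

Multiresolution archetypal decomposition and cell-state network analysis for
single-cell transcriptomics.

## The problem

Matrix decompositions of single-cell expression data force a choice of the
number of components `k`, but real tissues carry structure at several
resolutions at once: coarse lineages, discrete cell types, and activity
programs shared as gradients across types. No single `k` captures all of
them. `archenet` sidesteps the choice by decomposing at *every* resolution in
a range and then distilling the redundant pattern collection into a small,
nonredundant multiresolution set of cell states.

## The method

1. **Kernel reduction.** The genes × cells counts matrix `S` is passed
   through a gene-reweighting transform (library-size normalization, log1p,
   per-gene winsorized z-scoring) that damps ubiquitous genes and boosts
   cell-specific ones, then compressed by randomized SVD to a rank-`D`
   profile `S_r` with `S_rᵀS_r ≈ ZᵀZ`.
2. **Archetypal decomposition per resolution.** At each `k`, solve

       min_{C,H} ‖S_r − S_r C H‖²_F,   columns of C, H on the simplex,

   so every archetype `W = S_r C` is a convex combination of a few
   *influential cells*. The solver is seeded with the successive projection
   algorithm (separable NMF), making the whole path deterministic.
3. **Multilevel concatenation.** Factors for `k = 2…30` are concatenated
   into `C*`, `H*`, `W*` (`T = Σk = 464` patterns for 2…30).
4. **Multiresolution pruning.** Patterns whose influential-cell sets overlap
   beyond hypergeometric chance are linked in a pattern graph; Leiden
   communities become equivalence classes and each class keeps its
   lowest-resolution member. Hundreds of patterns reduce to tens of states,
   each with a dominance score (class size).
5. **Metric cell network.** Normalized columns of `H*` are treated as
   distributions; the cell distance is `δᵢⱼ = √JS(hᵢ‖hⱼ)` with base-2 logs
   (a true metric in [0, 1]). A k*-NN rule picks each cell's neighbor count
   from its local distance distribution, and kept distances become smoothed
   affinities `w = exp(−(δ−ρ)/σ)` with `Σw = log₂k`.
6. **Layout, colors, annotation.** The network is embedded in 2/3D by SGD on
   the fuzzy cross-entropy objective with a 0–100 *compactness* knob
   replacing the `(a, b)` kernel pair; 3D coordinates map to CIELAB colors.
   Cells are typed by diffused marker expression with permutation z-scores;
   missing labels are filled by propagation with a Chernoff-bound null;
   states are annotated by permutation enrichment of cell covariates.

A fully seeded synthetic benchmark (13 identity programs defining cell types
plus one activity program shared as a gradient across half the types,
negative-binomial counts at three noise levels) makes everything testable
without downloads.

## Worked example

`python examples/decompose_benchmark.py` prints:

```
simulated 500 genes x 325 cells, 14 planted programs
multilevel decomposition: T = 464 patterns across 29 resolutions
saturation (nontrivial patterns) at k = 5, 13, 20, 30: [5, 13, 17, 21]
pruning: 464 patterns -> 31 multiresolution states
programs matched one-to-one: 14 / 14
  program 0 -> state 17 (capture -log10 p = 41.9)
  program 1 -> state 12 (capture -log10 p = 26.8)
  program 2 -> state 6 (capture -log10 p = 30.2)
```

The saturation counts track `k` until the planted program count (14) and
then flatten — added resolution stops finding new patterns. Pruning reduces
the 464 concatenated patterns to 31 states, and every planted program
(including the shared activity gradient) is matched one-to-one by a distinct
state; a capture score of `s` means the state's encoding separates the
program's cells from the rest at Welch-t `p = 10⁻ˢ`.

The other example scripts cover archetype recovery on planted hull geometry
(`archetypal_geometry.py`), network construction, clustering, layout and de
novo coloring (`network_layout_colors.py`), and marker annotation plus label
propagation (`annotate_and_propagate.py`).

A thin CLI wraps the same library calls:

```bash
archenet simulate --seed 1 --out counts.csv
archenet run --input counts.csv --seed 1 --out results.h5 --export-csv exports/
```

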