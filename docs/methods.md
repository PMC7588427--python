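# Methods

## Model and assumptions

`archenet` treats a single-cell expression profile as a convex mixture of a
small set of extreme, prototypical states (archetypes). Archetypal analysis
factors the reduced profile `S_r` (D × cells) as `S_r ≈ (S_r C) H` with the
columns of `C` (cells × k) and `H` (k × cells) constrained to the
probability simplex. The convexity of `C` makes every archetype a sparse
local average of observed cells — its *influential cells* — and the
convexity of `H` makes each cell a distribution over archetypes. Because a
single `k` cannot capture coarse and fine structure simultaneously, the
decomposition is run independently at every `k` in a range and the results
are unified afterwards. The approach assumes (i) states are convex
combinations of observed cells in the reduced space, and (ii) patterns that
recur across resolutions with similar influential-cell sets are the same
biological state.

## Numerical procedures

**Kernel transform.** Counts are scaled per cell to the median library
size, log1p-transformed, and z-scored per gene with winsorization at ±10.
The exact reweighting chain is a design choice (recorded in the output
metadata so tests can pin it): centering removes uniformly expressed genes,
scaling up-weights cell-specific genes, and no highly-variable-gene
preselection is needed. Cells with zero counts are rejected; zero-variance
genes are kept as zero rows.

**Reduction.** Randomized SVD (scikit-learn; oversampling 10, 5 power
iterations, seeded) gives `S_r = Σ Vᵀ` and gene loadings `U`; default
`D = 50`. `S_rᵀS_r` is then the best rank-D approximation of the expression
kernel `ZᵀZ`. An externally batch-corrected reduced matrix can be supplied
in place of this step; no correction is implemented here.

**Single-level solver.** SPA picks `k` columns by iterated
maximum-residual-norm selection with orthogonal projection (ties to the
lowest index). Refinement alternates exact block updates: each column of
`H`, then each column of `C`, is a simplex-constrained least squares solved
by Lawson–Hanson NNLS on a penalty-augmented system (sum-to-one row with
weight 10³·max|A|) followed by exact renormalization; per-column updates are
exact minimizations, so the recorded objective trace is non-increasing.
Convergence: relative objective change < 1e-6 or 100 sweeps; coefficients
above 1e-5 count as "nonzero" for influence and saturation purposes.
Surplus archetypes whose encoding row carries no mass are never updated,
which is what leaves them at their one-hot initialization on saturated
data.

**Saturation.** The per-level count of nontrivial `C` columns (> 1 nonzero)
tracks `k` while genuine patterns remain undiscovered and then bends to
sub-linear growth. On negative-binomial benchmark data the bend sits at the
planted program count; the count keeps creeping upward slowly because an
exact solver will always harvest small residual gains by averaging a few
extreme cells, so the curve's slope change — not an absolute plateau — is
the usable signal.

**Metric and network.** Normalized multilevel encodings are compared with
the square root of the base-2 Jensen–Shannon divergence (a metric, bounded
in [0, 1]). Candidate neighbors (budget `min(N−1, max(30, ⌈√N⌉))`) are
retrieved by Euclidean search on square-rooted probability vectors (the
Hellinger embedding, which orders neighbors nearly identically) and
re-ranked by exact distance; the k* rule — run verbatim on κ-scaled
ascending distances, returning N−1 when the loop never breaks (equidistant
case) — fixes each cell's neighbor count; σ is solved by 64-step bisection
on `[1e-10, 10(δ_max−ρ)]` so smoothed weights sum to `log₂ k` within 1e-5
(`k = 1` keeps weight 1; an all-tied row saturates at weight 1 each). The
directed graph is symmetrized with `max(w_ij, w_ji)` to preserve
density-adaptive reach. κ defaults to 1.

**Pruning.** Pattern-graph edges require hypergeometric overlap
`p < 0.01`; weights are `−log₁₀ p` capped at 300. Leiden
(RBConfiguration, seeded) at resolution 8 forms the equivalence classes;
each class keeps its smallest-`k` member (ties: smallest within-level
index). The resolution default was chosen by an internal coherence
criterion — class members should share similar influential-cell sets, the
assumption that justifies keeping only the lowest-resolution member — at
low resolution coarse low-`k` patterns act as hubs chaining unrelated fine
patterns into scale-spanning classes, while beyond the chosen value the
classes splinter into hundreds of near-duplicates. At the default, a
multilevel space of ~464 patterns reduces to ~25–35 states on the
benchmark. A pattern supported by a single cell offers overlap evidence of
only `1/n_cells` and may stay unmerged; this is statistically faithful.

**Layout.** Spectral initialization from the symmetric normalized
Laplacian (seeded), then per-edge SGD on the fuzzy cross-entropy objective
with kernel `f(d) = 1/(1 + a d^{2b})`: attractive updates sampled
proportionally to edge weight, 5 negative samples per attractive update,
learning rate 1.0 with linear decay, 500 epochs, gradients clipped at ±4.
The compactness knob (0–100) maps log-linearly to a min-dist value in
[0.005, 0.5]; `(a, b)` are fit by nonlinear least squares to the smooth-step
target. Single-threaded and seed-deterministic. De novo colors: the
highest-variance 3D axis maps to L* ∈ [35, 85], the others to a*, b* ∈
[−40, 40]; L\*a\*b\* converts to sRGB with clipping; coincident coordinates
get identical colors and degenerate axes map to channel centers.

**Annotation.** Diffusion is the personalized-propagation fixed point
`x = (1−α)Px + αv` on the row-stochastic affinities, solved by power
iteration to 1e-6 (restart α = 0.15). Marker typing scores each cell-type
as the signed mean of diffused marker vectors against a null of random
same-size gene panels (diffusion is linear, so panels reuse the
once-diffused gene matrix); z-scores are invariant to global constant
offsets. Label propagation aggregates incident edge weights per label and
converts them to confidences with a Chernoff relative-entropy tail bound
against the global label frequency (monotone in evidence, zero without
enrichment); unlabeled cells adopt the strongest-evidence label, labeled
cells switch only when the challenger's confidence exceeds 2× the
incumbent's; updates are synchronous. State enrichment permutes cell order
(1,000 draws by default) and reports z-scores, with one-hot encoding for
categorical covariates and exact zeros for permutation-invariant inputs.

## Synthetic benchmark

The generator emulates the standard identity/activity simulation design: 13
identity programs, each a disjoint 15-gene marker block boosted 6-fold over
a lognormal baseline, each defining one cell type (25 cells per type, 325
cells, 500 genes); one activity program covering the first 7 types with
Uniform(0, 1) gradient loadings. Counts are negative binomial with
dispersion 0.1/0.5/1.5 for low/mid/high noise; the baseline rate (2.0,
≈1,300 counts per cell) was calibrated once so that low-noise recovery is
near-perfect, matching the benchmark's design intent. What the generator
does *not* emulate: doublets, ambient RNA, batch effects, library-size
heterogeneity beyond NB sampling, and gene–gene correlation within
programs — so passing tests demonstrate the machinery recovers planted
convex structure under count noise, not robustness to every real-data
artifact. Problem sizes (325 cells, D = 50, k ≤ 30) are desk-scale choices
that keep a full pipeline run under a minute while preserving the 464 →
tens pattern-reduction regime.

Recovery scoring: each planted program is compared against every recovered
state by the one-sided Welch t statistic (closed form, Welch–Satterthwaite
degrees of freedom; capped at −log₁₀ p = 300 for perfect separation) of the
state's encoding over program-positive versus remaining cells; programs and
states are matched greedily by descending score, one-to-one, and a program
counts as recovered at p < 10⁻³.

## Known limitations

- The solver is exact per block but the overall AA problem is non-convex;
  recovery guarantees hold only in the separable (hull-vertex) regime.
- The transform chain is a documented stand-in for the reweighting of the
  original expression-kernel construction, which is not restated here.
- Pattern-class structure depends on the community-detection resolution;
  the default favors scale-coherent classes over minimal state counts.
- The Hellinger candidate search can in principle miss exact-JSD neighbors;
  measured edge overlap with brute force exceeds 90% and distances on kept
  edges are always exact.
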