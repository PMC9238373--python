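# Methods

## Model and transforms

### Robust centered log-ratio (rclr)

For a sample `x` with observed (nonzero) index set `Ω_x`, the rclr of an
observed entry is `log x_i − log g_r(x)`, where `g_r(x)` is the geometric
mean over `Ω_x` only. Zeros are carried as *missing* (a boolean mask),
never imputed — on sparse sequencing data a zero is censoring, not a
measurement of absence. On a dense sample the rclr reduces exactly to the
classic clr, and it is invariant to per-sample rescaling (compositional
coherence). All logs are natural.

The "total" form of the transform removes both row (sample) and column
(feature) means over observed entries. On masked data no single pass
satisfies both at once, so `double_center` alternates row and column mean
removal until every observed-entry row and column mean is below `tol`
(default 1e-8, 100-iteration cap, warn-and-return on non-convergence; in
practice 5–20 sweeps suffice). We interpret the inner sums of the total
form as sums of *log* values (log geometric means): the raw-count reading
would not reduce to the clr on dense data, which the elementwise
definition requires. The pipeline split is deliberate: `rclr` performs
row centering only, and the column pass happens inside `double_center`
at the head of the factorization, so each contract is testable on its own.

### Phylogenetic rclr

Given a rooted tree with branch lengths whose tips cover the table's
features, the table is expanded Fast-UniFrac style: every non-root node
receives a column equal to the per-sample sum of its descendant tip
counts, ordered by postorder. Each sample is closed to proportions, each
node column is multiplied by the node's branch length, and the rclr is
applied to the weighted matrix. Consequences worth noting:

- **Root exclusion.** The root has no branch length; its column would be
  weightless and compositionally constant, so it is excluded.
- **Zero-length branches** produce a weighted value of 0 (log-undefined)
  and are dropped from the expansion rather than pseudo-lengthed.
- **Missing newick branch lengths** default to 1.0 with a logged warning.
- Because the rclr centers per sample, a *uniform* rescaling of all
  branch lengths cancels exactly; only relative branch lengths matter.
- A star tree with unit branches reproduces the plain rclr: the
  phylogenetic transform is a strict generalization.
- Unnamed internal nodes get stable ids `n<postorder-rank>` so loadings
  and log-ratios can reference them across runs.

## Masked low-rank factorization

`masked_factorize` completes the double-centered masked matrix at rank r
(default 3) by alternating least squares restricted to observed entries:
each sweep solves the exact per-row and per-column normal equations
(batched 3×3 solves), so the masked residual is nonincreasing; iteration
stops when the relative objective change falls below 1e-8 (cap 1000).
The normal equations carry a ridge of 1e-12 scaled by each system's mean
diagonal — without the scaling, columns observed in a single sample at
low sequencing depth produce numerically singular systems.

Initialization is a warm start from the SVD of the zero-filled matrix
plus a small (1e-3-scaled) seeded uniform perturbation. A purely random
cold start can stall on a degenerate ray of the masked objective (the
objective plateaus while the factors diverge — reproducible on a 2×2
rank-1 completion), whereas the warm start is robust, converges an order
of magnitude faster, and keeps the seeded-determinism contract: the same
seed yields bitwise-identical results.

The returned factors are the thin SVD of the completed reconstruction,
so scores and loadings are orthonormalized and the singular values play
the role of eigenvalues. Sample scores are `U·S`; beta-diversity distances
are Euclidean on those scores (the low-rank Aitchison-distance
convention; stated explicitly because other conventions — unscaled `U`,
loading-space distances — exist). `proportion_explained` divides each
squared singular value by the total observed sum of squares of the
centered matrix; because part of that total lives at masked entries
this is an approximation, clipped so the proportions never exceed 1.

Rare features can dominate: a feature observed in a handful of samples at
tiny proportions produces extreme rclr values, and a low-rank fit may
spend an axis on it. The `min_feature_count` filter (strict `>`,
inclusive variant available) is the standard mitigation and is applied
before the transform.

### CTF (repeated measures)

Samples mapping to (subject, state) pairs are arranged into a
subject × node × state tensor of double-centered (phylo-)rclr values,
with missing cells masked, and fitted with a masked CP decomposition by
the same alternating scheme (SVD-of-unfolding warm starts, seeded
perturbation, trace-scaled ridge). Subject scores are read from the SVD
of the subject-mode unfolding of the reconstruction, which makes a
one-state tensor reduce *exactly* to the matrix factorization — verified
by a Procrustes comparison against RPCA. States are unordered categories;
the factorization is aware of the repeated structure but not of temporal
order, and the per-state factor matrix is returned for inspection.

## Simulation model

The generator emulates a community with three environment blocks. Each
feature i carries a location `μ_i`, each sample j its block's location
`g_j`, and the pre-closure intensity is the Gaussian kernel
`exp(−(μ_i − g_j)² / 2σ²) / √(2πσ²)` — so features peak in their own
block's samples. A fraction of each block's features (default 10%) sits
between block centers, emulating taxa shared across environments.
Intensities are perturbed with additive Normal(0, `noise_sd`) and
Uniform(0, `noise_sd`) noise, clipped at zero, and closed per sample.
Counts are then drawn Poisson-lognormally:
`y_ij ~ Poisson(n · p_ij · exp(ε))`, `ε ~ Normal(0, φ²)`, which
overdisperses depth like real libraries; the expected per-sample total is
`n·exp(φ²/2)` (≈ 1.13·n at the default φ = 0.5).

Defaults: 3 blocks × 100 features, 20 samples/block, σ = 1, block centers
0/5/10, overlap 0.1, φ = 0.5, `noise_sd` = 0.01 (≈ 2.5% of the peak
kernel intensity 1/√2π — small enough not to drown the block structure,
large enough that no proportion is analytically exact). The companion
phylogeny is a caterpillar-of-clades whose postorder tip sequence equals
the block order (unit branch lengths), so phylogenetic signal and sample
structure are perfectly synchronized; `shuffle_proportion` desynchronizes
it by permuting a seeded random subset of tip labels
(k = round(q·T), fixed points allowed), and `use_random_tree` replaces it
with a seeded random-join tree carrying no signal at all.

What the simulation does *not* emulate: realistic feature-abundance
skew and richness (thousands of features, long tails), varying library
sizes within a study, and phylogenies with heterogeneous branch lengths.
Block separation under the defaults is strong, so classification-based
metrics saturate easily (see Limitations); passing benchmarks here shows
correct mechanics and directionality, not effect sizes transferable to
real data.

## Evaluation harness

- **PERMANOVA** pseudo-F on distance matrices (among/within sums of
  squared distances), computed through scikit-bio's seeded implementation
  behind this package's validation layer; p-values use the add-one
  permutation estimator with 999 permutations by default. Cross-checked
  in tests against the closed-form one-way ANOVA F on 1-D Euclidean data.
- **KNN classification** of ordination scores: first min(r, 3)
  components, 10 repeated seeded stratified splits at train fraction 0.5,
  k = 3 (clamped to the smallest training class with a warning), macro
  one-vs-rest average precision and ROC-AUC per split, averaged over
  splits. The per-split-averaged average precision (rather than a pooled
  curve) is a documented choice.
- **benchmark** sweeps depth × shuffle proportion × replicate seed for
  both methods over freshly simulated datasets, fully seeded.

## Log-ratios and annotation

`node_log_ratio` computes `log(Σ counts under num / Σ counts under den)`
per sample. Overlap is checked at tip-set level — on a tree, tip-set
overlap is equivalent to one node being the other's ancestor — and
rejected. Samples with a zero sum on either side are dropped and
reported, never pseudocounted: choosing dense clades is the intended way
to avoid drop-out. `lca_annotate` names a node by the longest common
rank-prefix of its tips' semicolon-delimited lineages.

`prune_tree` shears a tree to a feature subset, collapsing unary chains
with branch lengths summed (tip-to-root paths preserved); the optional
`min_subtree_tips` rule additionally collapses internal nodes spanning
fewer than the given number of retained tips, shrinking the expanded
feature space for large trees. The precise rule is this package's choice.

## Problem sizes

The shipped benchmark and test configurations use 3 × 100 features,
60 samples, 10 replicate seeds, and depths 200 and 2,000,000
reads/sample; a full sweep runs in well under a minute on one CPU. The
calibration test of PERMANOVA's type-I error uses 400 trials at 99
permutations (binomial standard error ≈ 0.011 around 0.05).

## Known limitations

- Under the default generator, plain RPCA already separates the three
  blocks nearly perfectly at high depth, so the phylogenetic F-statistic
  gain is consistently directional (phylo ≥ non-phylo across seeds) but
  modest (~1.3×), and KNN PR-AUC stays near 1.0 even at 200 reads/sample.
  Large published contrasts arise on sparser, more realistic tables than
  this desk-scale generator produces.
- Beyond the sharp drop from an unshuffled to a 25%-shuffled tree, the
  F-statistic response to further shuffling is flat to within replicate
  noise at this scale.
- The factorization offers no out-of-sample projection: new samples
  require refitting.
- The low-rank assumption itself can mislead on genuinely high-rank
  community structure; inspect `proportion_explained`.
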