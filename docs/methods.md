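# Methods

## Model and procedure

`tagine` treats feature engineering as a sequence of local nested-model
comparisons on the taxonomic tree. For a clade `v` with children
`c₁ … c_k`, the collapsed model regresses the binary label on the clade's
aggregated relative abundance; the expanded model regresses on the
children's abundances. Since `x_v = Σ x_{c_i}` by construction, the
collapsed model is a linear restriction of the expanded one (all child
coefficients equal), so the expanded maximized log-likelihood is never
lower and the AIC comparison is a penalized likelihood-ratio decision with
penalty 2 per extra parameter. Under the null of no child-specific signal,
the expanded model wins with probability ≈ P(χ²₁ > 2) ≈ 0.157 per extra
degree of freedom, which is the algorithm's false-expansion rate and is
asserted (with slack) in the test suite.

Wald pruning uses the two-sided normal-approximation p-value of each child
coefficient in the expanded fit. The significance level α is not dictated
by the method; 0.05 is the default and is exposed on the CLI, as is an
optional Benjamini–Hochberg adjustment across a node's children (off by
default: plain per-child significance is the primary behavior).

Decisions are local to a node and each node is examined at most once, so
the number of `compare_models` calls is bounded by the internal-node count
and the result is independent of queue discipline (FIFO and LIFO are both
implemented; the equivalence is tested on random instances). The selected
clades are mutually non-nested by construction — a node becomes a feature
only when its subtree's exploration stops there, and pruned subtrees are
never revisited.

## Estimation and numerical choices

Logistic fits are unpenalized maximum likelihood via Newton–Raphson (IRLS)
with step halving, at most 100 iterations and a gradient tolerance of
1e-8. The Newton step solves the normal equations by least squares, so
exactly collinear designs (e.g. two children that are each half their
parent; or children summing to a constant) converge to a
maximum-likelihood point instead of erroring; rank-deficient directions
receive infinite standard errors and therefore Wald p = 1, which prunes
them — the conservative resolution.

Complete or quasi-complete separation is flagged when any slope exceeds 30
on the standardized-predictor scale (a one-SD change moving the log-odds by
30 is far beyond any finite-MLE fit) or when the likelihood approaches its
supremum without gradient convergence. A separated or non-converged
*expanded* model keeps the node collapsed: the richer model's evidence is
unstable, and AIC's purpose is to penalize exactly that. The fallback is
recorded in the per-node decision log. Exact AIC ties keep the node
collapsed (parsimony). All-constant child columns are dropped from the
expanded design and marked non-significant.

When the AIC favors expansion but every child fails the Wald test, the
default keeps the clade collapsed as a single feature: the comparison
established that the clade carries signal even when individual coefficients
are unstable. A strict `drop_node` policy is available.

Predictors are the (pseudocounted, renormalized) relative abundances; an
optional natural-log transform is exposed (`--log-abundance`), safe because
the pseudocount guarantees strict positivity. Plain AIC is the default;
the small-sample AICc is behind a flag.

## Tree construction conventions

- An artificial root is always added, so "one level below the root" is
  well defined for single-kingdom data; depth counts from this root.
- Single-child chains (unassigned intermediate ranks) are compressed at
  build time into one node whose name concatenates the chain with `|`.
  A chain adds parameters without changing any clade's leaf set, so the
  information criterion could never favor expanding along it and the
  subtree below would be unreachable; compression preserves reachability
  without changing any likelihood. Real taxonomies leave this case
  unspecified; this is the package's own convention, applied uniformly.
- Placeholder rank tokens ("g__", "NA", "unclassified", "") are scoped
  under their parent: node identity is the full path, so unrelated
  "unclassified" taxa never merge.
- Children are ordered lexicographically by name for deterministic outputs
  and design-matrix column order.
- Initial-frontier features that are never expanded are included in the
  feature set unconditionally; significance pruning applies only to the
  children of expanded nodes.

## Preprocessing

Pipeline order: normalize → filter (training statistics) → renormalize →
half-minimum pseudocount → renormalize. The rare-feature thresholds (mean
abundance 1e-6, prevalence 1e-2) are interpreted on the relative-abundance
scale, which keeps them meaningful for raw-count input; a literal
filter-before-normalization order is available via `filter_on="raw"`.
"Minimum value in each sample" is read as the minimum *strictly positive*
value — half of an exact zero would leave zeros in place, defeating the
step's purpose. Prevalence is the plain fraction of training samples with
a non-zero value. Only the kept-feature list crosses from training to
held-out data; normalization and the pseudocount are per-sample
operations, so no statistics leak in either direction (asserted by a
perturbation test).

## Synthetic data: what it emulates and what it does not

The generator produces a rank-balanced random taxonomy (recursive
partition of species with per-level branching drawn from a configurable
range), i.i.d. per-sample log-normal species abundances with random zeros
(`sparsity`), compositional closure, and a binary label drawn from a
logistic model on the *standardized* aggregated abundance of one planted
clade, so `effect_size` is a log-odds per SD and recovery behavior is
comparable across table sizes. Defaults: 300 samples, 500 species, 5
ranks, branching 2–5, sparsity 0.3, effect 3.

The log-scale standard deviation defaults to σ = 1. This is within the
range of typical within-taxon variability and is the calibration under
which a planted standardized effect is actually learnable by
abundance-scale regressions; at much heavier tails (σ ≳ 2) a clade
aggregate's variance is dominated by single-sample outliers and *no*
method fitting abundances linearly can see the planted log-odds-per-SD
signal, which would conflate generator miscalibration with algorithmic
failure.

Features of real data the generator does not emulate: uneven species
abundance distributions (all species share one scale), correlation between
related taxa beyond shared-clade summation, structured (abundance-
dependent) zeros, batch effects, and compositional negative correlation
beyond closure. Passing recovery tests therefore demonstrate correctness
of the search under a clean planted-signal model, not expected performance
on any particular cohort.

One consequence worth stating: because the planted signal lives purely in
a clade aggregate spread over ~dozens of equal-scale species, the
no-selection random-forest baseline is structurally disadvantaged (each
species carries a small fraction of the signal), and the selection
algorithm's held-out AUC comes out substantially *higher* than the
baseline's on this benchmark rather than merely comparable. On real
cohorts, where species-level signal exists, the two are expected to be
close.

## Evaluation protocol

Repeated class-stratified random splits (default 50 repeats, 85%/15%);
preprocessing, tree construction, and feature selection on the training
samples only; a random forest (500 trees, fixed per-repeat seed; the
classifier is pluggable and the forest hyperparameters are not part of the
method) scored by rank-based AUC-ROC on the held-out samples. Paired
method differences are tested with the corrected resampled t-test —
variance factor `1/J + n_test/n_train` with `J − 1` degrees of freedom,
the corrected-resampled (not conservative-Z) variant — and all tests on a
dataset are adjusted by Benjamini–Hochberg step-up FDR. Splits are
stratified to guarantee both classes in every training set at small n.

## Problem sizes used in the bundled experiments

Reference-equivalence runs use 100 random instances with trees of ≤ 12
nodes; the no-nesting check 200 random instances of 8–40 species; recovery
rates 50 simulations each at 300 samples (500 species for the clade case,
40 for the species case); the compactness benchmark 20 paired splits at
300 samples × 500 species; the linear-work measurement trees of 100 to
10,000 leaves, with the expansion frontier seeded at the parent-of-species
level so that the number of tested nodes, not per-node detection power at
a fixed sample size, is what varies with tree size.

## Known limitations

- Greedy and local: a clade is explored only if every ancestor's expansion
  was accepted, so globally optimal feature trees are not guaranteed.
- Binary labels only; no regression or multi-class mode.
- Rank-based taxonomies only (no branch lengths, no tree inference); BIOM
  input is not currently supported — use the lineage TSV layout.
- Sensitivity to taxonomy misassignment is inherited from the input tree,
  though coarse-to-fine search makes the top-level decisions robust to
  fine-grained assignment errors.
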