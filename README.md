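# tagine

Taxonomy-aware greedy feature engineering for microbiome classification.

Metagenomic profiles routinely contain thousands of species-level features
for a few hundred samples, which invites overfitting and obscures
interpretation. The taxonomy linking those species offers a principled way
out: related taxa tend to be functionally similar, so informative signal
often lives at the level of a clade rather than a single species — but the
right level differs from clade to clade. `tagine` searches the taxonomic
tree for that level, clade by clade.

## The algorithm

Given a table of relative abundances `X` (samples × taxa), a binary label
`y`, and the taxonomic tree `T` whose leaves are the input taxa (internal
nodes carry the sum of their children's abundances), the search starts with
the tree collapsed to a coarse frontier (by default one level below the
root) and a FIFO queue `Q` of frontier nodes. For each node `v` popped from
`Q`, two logistic regressions are fitted:

* **collapsed** — `logit P(y=1) = β₀ + β₁ x_v`, where `x_v` is the clade's
  aggregated abundance (2 parameters);
* **expanded** — `logit P(y=1) = β₀ + Σ_c β_c x_c` over the children `c` of
  `v` (1 + |children| parameters),

and compared by AIC = 2k − 2 ln L. Because the children sum to the parent,
the collapsed model is nested in the expanded one; the AIC penalty is what
stops indiscriminate splitting and removes any bias toward many-children
nodes. If the expanded model does not win, `v` stays collapsed and becomes
a final feature (its descendants are never examined). If it wins, children
whose Wald two-sided p-value is ≥ α (default 0.05) are pruned from `T` and
never revisited; surviving internal children join `Q` and surviving leaves
become final features. When `Q` empties, the leaves remaining in `T` —
a mix of taxonomic levels — are the feature set, and the pruned tree itself
is returned as an interpretable artifact.

Each inner node is examined at most once, so the number of model fits is
bounded by the number of internal nodes: work is linear in the number of
input features. No selected feature is an ancestor of another, so every
microbe contributes its abundance to exactly one feature.

Preprocessing follows standard compositional practice: normalize each
sample to relative abundances, drop features with mean abundance < 1e-6 or
prevalence < 1e-2 (statistics from the training samples only), renormalize,
then add half of each sample's minimum positive value to all entries and
renormalize again, leaving a strictly positive composition.

## Worked example

Simulate a 300-sample, 500-species cohort with a class signal planted on
one depth-2 clade, then run the selection:

```
$ tagine simulate --seed 5 --out-prefix demo/
wrote demo/table.tsv / metadata.tsv / provenance.json (planted clade: k__t4;p__t17)

$ tagine run --table demo/table.tsv --metadata demo/metadata.tsv \
             --label-col label --out-dir demo/results
filter: kept 500 of 500 features
node k__t1: AIC 414.480 vs 420.848 -> keep collapsed
node k__t2: AIC 416.705 vs 418.437 -> keep collapsed
node k__t3: AIC 415.938 vs 421.053 -> keep collapsed
node k__t4: AIC 408.689 vs 232.483 -> expand (pruned 4)
node k__t4;p__t17: AIC 231.178 vs 234.644 -> keep collapsed
selected 4 feature(s) with 5 model comparisons
4 features -> demo/results
```

Reading the log: the four kingdom-level frontier nodes are each tested
once. Only `k__t4` benefits from splitting (its AIC drops from 408.7 to
232.5); four of its five phyla are Wald-pruned, and the surviving phylum
`k__t4;p__t17` — exactly the clade the simulation planted the signal on —
is then kept whole, since splitting it further only adds parameters. The
result: 4 clade features in place of 500 species, with `features.tsv`
(aggregated abundances with taxonomic paths), `pruned_tree.nwk` (Newick),
and `decisions.json` (the full per-node audit trail) written to
`demo/results/`.

`tagine benchmark` runs the evaluation protocol — repeated stratified
85%/15% splits, a downstream random forest, AUC-ROC, and paired
Nadeau–Bengio-corrected t-tests with Benjamini–Hochberg FDR — against
baselines (`none`, `all-levels`, `fixed-level:<depth>`, optional `rfe`).

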