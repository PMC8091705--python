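# Methods

## Model and procedure

`stableflow` addresses feature instability of sparse linear classifiers on
high-dimensional genotype matrices. The procedure has five stages.

**1. Encoding.** Genotypes become a binary samples × variants matrix: a cell
is 1 when the sample carries at least one alternate allele (heterozygous or
homozygous alternate), 0 when it matches the reference. Missing genotypes
(`./.` and half-calls) are encoded 0 — a presence indicator should not
assert presence without evidence. Multi-allelic records are split into one
biallelic column per alternate allele so each column has a single
`chrom:pos:ref:alt` identity. BED region filtering converts the 0-based
half-open BED convention to the 1-based variant coordinate exactly once, at
the filter boundary: position p is kept iff start < p ≤ end.

**2. Per-fold selection.** A stratified 80/20 train/test split is followed
by stratified k-fold cross-validation (k = 5) on the training set. For each
fold the classifier is fit on the k−1 complementary folds and the variants
with non-zero coefficients form that fold's selection. Supported selectors:
L1 logistic regression, elastic-net logistic regression, L1 linear SVC.
Regularization is parameterized by λ, the penalty weight; backends using the
inverse convention receive C = 1/λ. Class weights can be set inversely
proportional to class sizes for imbalanced cohorts (off for the balanced
simulations).

**3. Stability metrics.** For each of the k(k−1)/2 fold pairs:

- *Pearson* correlation of the coefficient vectors aligned on the **union**
  of the two selections, with unselected variants contributing 0. The union
  rule penalizes selection disagreement; computing only over the
  intersection would overstate stability by conditioning on agreement.
- *Kendall-Tau* as (P − Q)/(P + Q) over concordant/discordant pairs of the
  union-aligned rankings. Variants are ranked by signed coefficient; ties
  (including the zeros of unselected variants) are broken by lexicographic
  variant id, giving a strict total order and a deterministic statistic.
  This is implemented in-repo by direct pair counting because library
  implementations (tau-b) treat ties differently.
- *Jaccard* |A∩B|/|A∪B| of the selected id sets (1 for two empty sets, by
  convention, logged).

**4. Flow network.** Selections become layers of a k-partite graph; an edge
joins (v₁, f) → (v₂, f+1) iff the variants share a chromosome and are
identical or have R² strictly above 0.8. LD is the squared Pearson
correlation of the two feature columns, computed on the **training samples
only** (the population the selector saw; this also keeps held-out data out
of the network construction). On binary presence columns this equals the
classical genotype r² = D²/(p_A p_a p_B p_b); on continuous simulated
features it is plain squared correlation. R² is evaluated lazily, only for
cross-fold candidate pairs within one chromosome — never genome-wide.

Each node is split into an in/out pair joined by a unit-capacity edge
(vertex capacity → edge capacity), the source feeds fold-1 in-nodes, fold-k
out-nodes drain to the sink, and all capacities are 1. Maximum flow is
computed by an in-repo Ford–Fulkerson: repeated depth-first augmenting-path
search over the residual network, including reverse edges — a pure greedy
forward search is incorrect on crossing chains. With unit capacities each
augmentation adds one unit and the flow is bounded by the node count, so the
cost is O(VE). Neighbour order during the search is a seeded shuffle of the
id-sorted adjacency lists: the flow *value* is invariant to the seed (it is
the max-flow/min-cut optimum), while the particular path set — like any
Ford–Fulkerson tie-break — may vary with it; the seed makes that variability
explicit and reproducible. Flow decomposition walks flow-carrying edges from
the source, consuming them; the node split guarantees the resulting paths
are node-disjoint, each spans folds 1..k, and each carries 1–k unique
variants.

**5. Grouping and re-training.** Each path's deduplicated variants form one
grouped feature. On binary matrices the grouped column is the presence OR: 1
iff the sample carries at least one member variant. On continuous simulated
matrices it is the mean of the member columns — members are noisy copies of
a common source, so the mean is the natural region-level signal, and
thresholding mean-centred Gaussian features at zero would discard most of
their information. The classifier is refit per CV fold on the grouped
matrix with the same family and λ but an **L2** penalty: the point of the
post-flow stage is to measure coefficient agreement on a *fixed* feature
set, and an L1 refit could re-introduce selection (zeroing some groups in
some folds), breaking the structural Jaccard = 1 that the grouped design
establishes. Held-out precision, recall and AUC-ROC (decision-score based)
are computed on the grouped test matrix.

**Bootstrap null.** To check that non-zero flow is not a sampling artifact,
the five selections are replaced by uniform random variant sets of the same
sizes, the network is rebuilt and the flow recomputed, 100 times. On sparse
LD pools every iteration yields flow 0: random draws almost never place
linked variants in adjacent folds.

**Fold-ordering sensitivity.** The fold layers are ordered by CV index by
default; because the edge criterion links only neighbouring layers, the
graph — and potentially the flow — depends on that order. An explicit
permutation argument re-layers the graph for any ordering; the analysis
reports per-ordering flow values and the mean pairwise count of shared
variants between orderings' extracted sets.

## Synthetic data generator

The generator reproduces the statistical structure used to validate the
method, not population-genetic realism (no allele-frequency spectra,
recombination maps or coalescent structure):

1. **Base dataset** — `sklearn.datasets.make_classification`: clusters at
   hypercube vertices with unit-variance Gaussian scatter, balanced classes,
   `n_informative` columns carrying class signal (default 5% of features)
   and the rest label-independent noise. Columns are standardized to unit
   variance. Rows are reshuffled so class is not confounded with order.
2. **Chromosome groups** — features are randomly partitioned into 23
   non-empty groups of arbitrary sizes.
3. **LD injection** — each feature independently, with probability p
   (the "correlation level": 0.2/0.5/0.8 in the experiments), is replaced by
   a uniformly chosen *other* member of its group plus N(0, noise_sd²)
   noise. Copies read from the pre-injection matrix so chains of copies do
   not compound noise. With unit-variance features and noise_sd = 0.1 a copy
   has R² ≈ 1/(1 + 0.1²) ≈ 0.99 with its source, comfortably above the 0.8
   edge threshold.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_samples | 500 | the method targets regimes with ≥ 2–5× more features than samples; 500 samples at 1000–5000 features sits in that regime |
| n_features | 1000 | smallest experiment dimensionality |
| n_informative | 5% of features | "small effect sizes" spread over many features, as in polygenic data |
| correlation_level p | 0.5 | middle experimental level |
| noise_sd | 0.1 | keeps copies above the LD threshold (see above) |
| n_chromosome_groups | 23 | human karyotype count |
| λ (L1) | 10 | strong shrinkage: a small core of selected variants |
| λ (elastic net) | 100 / 1000 | correlation / dimensionality experiments respectively |
| elastic_net_mixing | 0.1 | at λ = 100 the effective L1 weight λ·mixing = 10 matches the pure-L1 setting; at 0.5 the elastic net selects essentially nothing at these sample sizes, a degenerate selector |
| LD threshold | 0.8 | conventional strong-LD cutoff |
| k | 5 | five validation folds |
| repeats per grid cell | 20 | experiment repetition count |

What passing simulations do **not** show about real data: the generator has
no rare variants (LD estimates on real rare variants are unstable), no LD
decay with distance (copies are equally likely anywhere within a group), no
population structure or batch effects, and its "variants" are continuous
features rather than presence indicators. Results on it validate the
machinery — selection, LD linking, flow, grouping — not cohort-level claims.

## Numerical choices

- Convergence: iteration cap 10,000, tolerance 1e-6; a failed fit is
  retried once with a 10× cap before erroring.
- Undefined metrics return NaN (never a silent 0): Pearson with a
  zero-variance aligned vector, Kendall-Tau with fewer than two items,
  AUC on a single-class test set, R² with a zero-variance column (such LD
  pairs are treated as unlinked).
- R² is clipped to [0, 1] against floating-point overshoot; the threshold
  comparison is strict (R² = 0.8 exactly draws no edge).
- Identical variant ids in adjacent folds short-circuit to R² = 1 without
  computation — a variant is trivially in LD with itself.
- Tie-breaks everywhere are lexicographic on variant id, making reports
  byte-reproducible under fixed seeds.
- Degenerate inputs: an empty fold yields an empty layer and flow 0 (with a
  warning); flow 0 completes the pipeline with empty groups and skips the
  post-flow stage; an empty region-filter intersection is a valid empty
  matrix, not an error.

## Design choices on genuinely open points

- **Union alignment** for Pearson/Kendall-Tau (vs intersection or the full
  feature set): punishes disagreement, matching the observation that low
  Jaccard co-occurs with only moderate Pearson.
- **LD on training samples** (vs full cohort): avoids test-set leakage into
  the network construction.
- **L2 refit at the same λ** for the post-flow stage: see stage 5 above.
- **Missing genotypes → 0**: conservative for a presence indicator.
- **Copy-from-base injection**: keeps pairwise R² interpretable
  (copy-of-copy chains would compound noise and blur the correlation level).
- **Grouped continuous features = member mean**: see stage 5 above.

## Problem sizes

The test suite exercises the full pipeline at 500 samples × 1000 features
(the smallest experiment cell), the stability-direction comparison at 10
repeats per model family, and the bootstrap null at a 50,000-feature pool
with 100 iterations; these sizes keep a full run of suite plus acceptance
script within a few minutes on one CPU while preserving every qualitative
regime (features ≫ samples, sparse LD pool, three model families). The
library itself has no size limits beyond memory; the flow step is linear in
edges per path and the LD step is restricted to cross-fold candidate pairs.

## Known limitations

- The flow formulation links only *neighbouring* folds; a variant selected
  in folds 1, 3 and 5 but not 2 and 4 contributes nothing. Stability is
  therefore measured against the specific fold sequence, and the
  fold-ordering analysis quantifies how much the extracted set moves.
- Ford–Fulkerson path decomposition is not unique; the traversal seed pins
  one decomposition but different seeds may extract overlapping-but-distinct
  variant sets (the flow value itself never changes).
- The LD estimator is squared Pearson correlation of presence columns; it
  does not model phase, D′, or haplotype structure.
- The pipeline assumes the input matrix already passed upstream quality
  control (variant calling, batch-effect filtering); it performs none.
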