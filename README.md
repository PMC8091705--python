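# stableflow

Stability selection for genomic classifiers, constrained by linkage
disequilibrium and solved as a maximum-flow problem.

## The problem

Sparse linear classifiers (L1-regularized logistic regression, linear SVC)
are widely used to pick disease-associated variants out of whole-genome
feature matrices. On high-dimensional genotype data the selected feature set
is notoriously unstable: retrain on a slightly perturbed training set and a
substantially different set of variants comes back, even though predictive
accuracy barely moves. A major cause is linkage disequilibrium (LD) — blocks
of strongly correlated variants among which the sparsity penalty picks an
essentially arbitrary representative, a different one in every fold.

`stableflow` turns that failure mode into signal. The per-fold selections of
a k-fold cross-validation are arranged as the layers of a k-partite graph:
node (v, f) means variant v received a non-zero coefficient in fold f, and
an edge joins (v₁, f) → (v₂, f+1) when the two variants lie on the same
chromosome and are either identical or in LD (R² > 0.8). Each graph node is
split into an in/out pair joined by a unit-capacity edge, a source is wired
to fold-1 nodes and a sink to fold-k nodes, and the maximum flow — computed
with Ford–Fulkerson over the residual network — counts the maximum number of
**node-disjoint chains of mutually linked variants that persist across every
fold**. Each unit-flow path is collapsed into one grouped feature (the OR of
its variants' presence indicators), and the classifier is refit on the
grouped matrix. The grouped feature set is identical in every fold, so the
Jaccard instability vanishes by construction, and coefficient agreement
(Pearson, Kendall-Tau) rises sharply.

The package provides, as library + CLI:

- VCF → binary presence matrix encoding with BED region filtering
  (`io_formats`);
- a synthetic-data generator emulating the statistical structure of
  chromosome-grouped, LD-correlated case/control data (`synthetic_data`);
- per-fold sparse selection and the three pairwise stability metrics —
  Pearson on union-aligned coefficients, Kendall-Tau = (P−Q)/(P+Q),
  Jaccard on the selected sets (`selection_stability`);
- within-chromosome R² computation (`ld`);
- the k-partite flow network, an in-repo unit-capacity Ford–Fulkerson,
  path decomposition and a bootstrap null test (`flownet`);
- end-to-end orchestration, grouped-feature re-training, held-out
  evaluation, simulation experiment grids and fold-ordering sensitivity
  analyses (`pipeline`, `cli`).

## Worked example

Simulate a 500 × 1000 two-class matrix in which half the features are noisy
copies of another feature from the same chromosome group, then run the whole
pipeline at λ = 10:

```bash
stableflow simulate --n-samples 500 --n-features 1000 --correlation 0.5 \
    --seed 7 --out m.tsv
stableflow select --matrix m.tsv --lambda 10 --k 5 --seed 7 \
    --out folds.tsv --train-out train.tsv
stableflow stability --folds folds.tsv --out report.tsv
stableflow flow --folds folds.tsv --matrix train.tsv --seed 7 --out groups.tsv
```

which prints

```
wrote 500 x 1000 matrix to m.tsv
selected [55, 51, 55, 52, 54] variants across 5 folds -> folds.tsv
pearson: min=0.709 max=0.940 mean=0.824
kendall_tau: min=0.422 max=0.530 mean=0.480
jaccard: min=0.282 max=0.432 mean=0.362
flow value 19; 19 groups, 22 distinct variants; edges: {'cross_fold': 124, 'split': 267, 'source': 55, 'sink': 54}
```

Reading: each fold selects ~54 of 1000 features but any two folds share only
about a third of them (Jaccard 0.36) — the classic instability picture. The
flow network finds 19 node-disjoint LD chains that persist across all five
folds, touching 22 distinct variants. `stableflow run-all --matrix m.tsv
--lambda 10 --seed 7 --out-dir run` then refits on the 19 grouped features
and reports

```
"post_stability": pearson mean 0.984, kendall_tau mean 0.869, jaccard 1.0
"heldout":        precision 0.836, recall 0.920, auc_roc 0.963
```

— coefficient stability jumps (Pearson 0.82 → 0.98, Kendall-Tau 0.48 → 0.87,
Jaccard 1.0 by construction) while held-out accuracy is preserved.

The bootstrap null (`stableflow bootstrap`) shows the chains are not a
sampling artifact: replacing the five selections with random variant sets of
the same sizes yields a maximum flow of 0 in every iteration, because random
draws from a large pool almost never place linked variants in neighbouring
folds.

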