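# pgxlink

Suggesting valid **pharmacogenes** — genes involved in inter-individual
drug-response variability — by learning from biomedical linked data.

Pharmacogenomic knowledge bases annotate gene–drug pairs with an evidence
level from 1 (well validated) to 4 (weakly supported). `pgxlink` treats
the weakly supported pairs as a prioritization problem: build a typed
linked-data graph of genes, drugs and phenotypes from several sources,
learn what distinguishes well-validated pairs from random gene–drug
combinations, and rank the uncertain candidates.

Two complementary learning branches are implemented:

* **Path features + random forest.** Each pair is described by its
  length-1 paths: gene attributes (pathway-like), drug attributes
  (ATC-like codes), direct gene–drug links, and — for every phenotype
  reachable from both members — the (gene–phenotype predicate, phenotype,
  drug–phenotype predicate) triple. The cartesian product of observed
  slot values makes one categorical row per combination, so a pair is a
  *bag* of instances B_i. Instance probabilities p_ij from the forest are
  aggregated by a signed weighted mean

      p_i = (1/n_i) Σ_j a_j · p_ij,   a_j = +1 if Class_ij = 1 else −1,

  which lands in [−1, 1] and, unlike `max` or the plain mean, pushes bags
  that mix confident positive and confident negative instances toward 0.

* **Graph kernels + SVM.** Artificial pair nodes linked to their gene and
  drug are classified by substructure-count kernels: edges are reified
  into labeled vertices, a depth-bounded neighborhood (subgraph, or tree
  with cycles unfolded) is extracted around each pair node, and bags of
  labels, walks, or Weisfeiler–Lehman-style refined subtrees are counted
  into sparse vectors whose dot products form a PSD kernel for a C-SVC.
  A global minimum-frequency filter removes one-off labels that do not
  generalize.

Both branches are evaluated with 10×10 repeated stratified
cross-validation at the pair level (bags never straddle folds), with SVM
hyperparameters chosen by inner 10-fold CV. Candidate pairs scored by
both branches are combined by intersecting the two top-k lists and
sorting by descending forest score.

Because the original multi-source corpus includes license-restricted
databases, the package ships a seeded synthetic generator that emulates
the schema — two namespaces per entity type with equivalence mappings,
typed predicates, attribute vocabularies — and plants a configurable
association signal, so every stage is testable end to end at desk scale.

## Worked example

```python
import pgxlink as px
from pgxlink.synth import SynthConfig, generate

g, truth = generate(SynthConfig(seed=1))          # ~750 nodes, ~2100 edges
train = truth.positive_pairs + truth.negative_pairs  # 95 vs 190 pairs

rf = px.forest_cv(g, train, folds=10, repeats=10, seed=1)
gk = px.kernel_cv(g, train, folds=10, repeats=10, seed=1)
print(f"forest weighted F {rf.weighted_f:.3f}  AUC {rf.auc_roc:.3f}")
print(f"kernel weighted F {gk.weighted_f:.3f}  AUC {gk.auc_roc:.3f}")

ranked, rf_scores, gk_scores = px.rank_candidates(g, train, truth.test_pairs, seed=1)
for r in ranked[:3]:
    print(r.rank, r.gene, r.drug, round(r.p_rf, 3), round(r.p_gk, 3))
```

prints

```
forest weighted F 1.000  AUC 1.000
kernel weighted F 0.884  AUC 0.932
1 genea:G0073 druga:D0033 1.0 0.93
2 genea:G0191 druga:D0064 1.0 0.799
3 genea:G0095 druga:D0089 1.0 0.794
```

The forest recovers the planted association signal essentially perfectly
(its bag representation joins gene-side and drug-side paths on the shared
phenotype); the kernel branch, linear in substructure counts, plateaus
lower — the same ordering-with-gap the method shows on real data. The
ranked list contains the level-3/4 candidates surfaced by *both*
branches; p_RF is the signed bag score and p_GK the calibrated SVM
probability, so values near 1 mean both models are confident the pair is
pharmacogenomically associated.

A CLI mirrors the library (`pgxlink synth`, `build-graph`, `make-sets`,
`featurize`, `kernel`, `rank`); see `pgxlink --help`.

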