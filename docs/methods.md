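# Methods

## Problem and data model

The package frames pharmacogene suggestion as link prediction on a typed
linked-data graph with three entity types — Gene, Drug, Phenotype — and
five edge families: gene–phenotype (SO-coded variant/association
predicates), drug–phenotype (indication, side effect), gene–drug
(target-style relations), entity→attribute edges (pathway-like gene
annotations, ATC-like drug codes, optional MeSH-like disease classes),
and cross-source equivalence mappings. Entities of the same type coming
from different sources keep separate nodes; equivalence is inferred by
applying per-namespace regular expressions to URIs and declaring a
mapping whenever two same-type nodes share the extracted identifier.
Mappings are applied either as symmetric `mapped_to` edges (default —
provenance is preserved and kernel walks may traverse the mapping) or by
contracting each equivalence class to its canonical member (offered for
the path-feature branch; the multiset of non-mapping edges is conserved
and the result is independent of mapping order).

Candidate gene–drug pairs become artificial nodes with two outgoing
structural edges, to their gene and their drug. Because pair nodes are
created with outgoing edges, they are already neighborhood roots from
which the rest of the graph is reachable, so the default edge-direction
inversion list is empty; `normalize_directions` remains available as a
config knob for graphs whose predicates point the other way (every
inverted predicate `p` is renamed `p_inv`, and a second application
restores an isomorphic graph). Labeled training pairs additionally point
at one of two class nodes (`associated` / `not_associated`; underscore
because URIs cannot contain spaces). **Class-membership edges are
stripped before kernel computation** — they exist to phrase the task as
node classification, but leaving them in the neighborhood would hand the
classifier its own labels under cross-validation.

Serialization is N-Triples via rdflib, with node types written as
`rdf:type` statements so isolated nodes and typing survive a round trip;
type statements are read back as typing, not data edges. Blank nodes are
rejected — the schema has no use for them. Since RDF graphs are
statement sets, the generator never emits duplicate triples.

## Training and test corpora

Source annotations relate gene *variants* to drugs at evidence levels
1–4 (1 = best validated). Variant annotations collapse to gene level
keeping the numerically smallest (strongest) level. Level-1/2 pairs are
the positives; level-3/4 pairs form the unknown test set to be ranked;
negatives are sampled uniformly without replacement from the
gene × drug pools of the seed table, minus an exclusion list of known
interactions, with sorted-then-shuffled draws under an explicit seed so
results are platform-stable. Positives, negatives and test pairs are
pairwise disjoint, and negatives are exhaustively checked against the
exclusion list. No special handling is applied to test pairs that share
a gene or drug with training pairs (the protocol it reproduces is silent
on this).

## Synthetic study conditions

The generator emulates an assembled multi-source corpus at desk scale:
200 genes, 100 drugs, 300 phenotypes; a fraction (0.2) of each entity
type duplicated in a second namespace with mapping edges; ~95 positive
pairs against ~190 negatives, echoing the 1:2 design of the seed corpus,
plus 40 level-3/4 test pairs, half of them true candidates. Background
structure: 1–2 pathway attributes per gene, one ATC code per drug, and
Poisson(2) noise edges per entity for gene–phenotype, drug–phenotype and
(at half that rate, scaled by entity count) gene–drug relations.

The association *signal* is the probability that a positive (or
signal-carrying test) pair receives its structural footprint:

* two shared **drug-response phenotypes** drawn from a dedicated pool of
  25 phenotypes — pharmacogenomic annotations concentrate on a small
  response/toxicity vocabulary, and established pairs typically carry
  several annotations (efficacy, toxicity, dosage). Each planted
  phenotype is wired with 1–2 gene-side SO predicates and 1–2 drug-side
  indication/side-effect predicates, attached to canonical-namespace
  nodes (curated sources reference standard identifiers; background
  edges may hit a provenance twin instead);
* one direct target-style gene–drug edge.

The exclusion list used for negative sampling contains every pair wired
with a gene–drug edge or planted signal, **plus interaction-screen
records**: for each footprint gene, each drug is listed with coverage
0.95. This models a gene-organized screen that aggregates known *and
predicted* interactions from many databases quasi-exhaustively, and it
reproduces the selection bias of checking candidate negatives against
such a screen: a random pair touching a well-known pharmacogene is
likely listed and therefore rarely becomes a negative — with the
corollary, acknowledged for the real corpus too, that negatives are
biased toward truly unrelated entity combinations.

What the generator does *not* emulate: real degree distributions,
vocabulary sizes, literal-valued attributes, or annotation noise in the
evidence levels themselves. Passing tests therefore show that the
pipeline recovers a planted relational signal under realistic schema and
selection-bias conditions — not that it would reach the same numbers on
the licensed corpus.

Determinism: a single `numpy` generator seeds everything; equal configs
give byte-identical fixture files.

## Path-feature branch

One categorical row per element of the cartesian product of the
non-empty slot value sets: gene attributes × shared-phenotype triples ×
drug attributes × direct gene–drug links (plus an optional disease-
attribute slot, off by default because it contributes almost no
information gain and was dropped in the protocol this follows). Slots
with no values contribute the reserved token `NA`; a fully isolated pair
yields one all-NA row, so pairs are never silently lost. Slot values are
read through the equivalence closure of each entity. Phenotype slots are
restricted to phenotypes shared by the pair's gene and drug; the
alternative (independent phenotype enumeration) explodes the matrix
quadratically without adding pair-level information.

Encoding is one-hot over a vocabulary frozen on the training rows; every
slot always carries an `NA` column and unseen test values fall back to
it, so test matrices share the training column space exactly.
Information gain H(class) − H(class|slot) is computed in bits on the
categorical slots (labeled rows only) and a threshold filter drops
uninformative slots from training and test encodings alike.

The forest is scikit-learn's `RandomForestClassifier` (100 trees,
seeded). Per-instance positive-class probabilities are turned into
(p_ij, Class_ij) with Class_ij = [p ≥ 0.5] and p_ij the probability of
the predicted class, then aggregated by the signed weighted mean into
p_i ∈ [−1, 1]. For threshold-based metrics the display transform
(p_i + 1)/2 is used; the raw signed score is reported in rankings.

## Graph-kernel branch

Reification turns each edge occurrence (u, p, v) into u → node(p) → v
(|V|+|E| vertices, 2|E| edges), so predicates count like vertex labels.
Neighborhoods around each pair node are extracted to depth d counted in
reified edges (d = 4 spans two original predicates plus the entities
between them): *subgraph* mode keeps each vertex once (BFS within d,
induced adjacency); *tree* mode unfolds cycles, repeating revisited
vertices as fresh occurrences, with a configurable occurrence cap whose
excess is an error, never silent truncation. Children are ordered by
label then identifier, so extraction is deterministic.

Three substructure families are counted into sparse vectors:

* bag of labels — vertex-occurrence label multiset;
* walks — label sequences of directed walks of length 0..l, counted with
  multiplicity (dot products need realization counts, not presence
  bits); length-0 walks (bare labels) are included behind a flag;
* subtrees — iterative Weisfeiler–Lehman-style refinement: at iteration
  h a vertex's label becomes (own label, sorted multiset of children's
  iteration-(h−1) labels), canonicalized as a string and tagged with h;
  all iterations 0..depth are counted. The refinement is validated
  against a brute-force recursive canonicalization oracle on random
  graphs (exact equality, 200 graphs ≤ 12 vertices).

The minimum-frequency filter computes label frequencies globally over
all instances' neighborhoods (per-instance filtering would break kernel
comparability); rare labels are dropped from bags and replaced by a
generic token inside walk/subtree patterns, so increasing the threshold
never grows any vector's support.

Defaults: tree neighborhood, subtrees, d = 4, l = 4, min_frequency = 8,
cosine normalization. These follow the setting ranking observed in the
source protocol (tree + subtrees best; depth largely irrelevant with the
informative features within distance 4; a moderate minimum frequency
helps because one-off labels are entity identifiers that memorize rather
than generalize).

Kernels are dot products of the sparse count vectors, symmetrized and
optionally cosine-normalized (all-zero vectors get diagonal 0); PSD is
checked to eigenvalue tolerance 1e−9. The SVM is a C-SVC on the
precomputed kernel; C is selected per outer fold by inner 10-fold CV
scored on prevalence-weighted F, and a logistic sigmoid fitted on the
inner-fold decision values calibrates p_GK (only rank fidelity is
required of it). Non-PSD kernels beyond tolerance are an error.

## Evaluation protocol

Stratified 10-fold CV repeated 10 times; each repeat's fold assignment
is seeded with (repeat index XOR base seed), so repeats are individually
reproducible. Folds are assigned on unique pair identities — duplicated
pairs co-fold — and a guard asserts on every run that no bag's instances
straddle a fold boundary. Reports carry per-class precision/recall/F,
prevalence-weighted and macro F (both, since protocols differ on which
"average F" means), AUC-ROC (absent for single-class truth), RMSE of the
positive-class probability, and per-repeat dispersion.

Ranking: both branches score the unknown pairs, the two top-k lists
(k = 20 by default) are intersected, and the intersection is sorted by
descending p_RF with ties broken by descending p_GK then pair id. The
signed forest score is reported unrescaled.

## Numerical and degenerate-input choices

Empty bags are an error at aggregation (a pair with no instances must
not be scored silently), but unknown test pairs whose bags come back
empty are scored as a single all-NA row with a warning. Single-class
training folds are an error for both learners. Kernel symmetry tolerance
1e−12; PSD tolerance 1e−9. Tree unfolding cap 1e5 occurrences.
Sampling uses sorted candidate enumeration before seeded shuffling, so
results do not depend on hash order.

## What the fixtures show, and known limitations

With the full planted signal the forest branch reaches weighted F ≈ 1.0
and the kernel branch ≈ 0.9 under the full protocol; with the signal off
both sit at AUC ≈ 0.5. The gap between branches is structural, not a
tuning artifact: a dot-product kernel is linear in substructure counts,
and "the same phenotype is reachable from both members" is a
coincidence-of-identity feature that no linear functional of label
counts can express. The bag representation encodes that join explicitly,
which is why the forest saturates. Negatives that combine a footprint
gene with a footprint drug would be exactly such linearly-invisible
cases; the interaction-screen exclusion removes most of them, and the
kernel's residual errors are screen-coverage slips plus background
annotations that collide with the response-phenotype pool by chance.

The CV protocol sizes used throughout (10×10 outer with repeat
randomization seeds 1..10, inner 10-fold, and 5 generator seeds for the
design-space comparisons) are the package's committed evaluation
conditions.
Scores on the synthetic benchmark say nothing quantitative about
license-restricted corpora; only orderings (tree + subtrees ≥ bag of
labels; root constraint harmful; forest below kernel on real data but
above it here) should be compared qualitatively.
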