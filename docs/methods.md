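# Methods

## Model and assumptions

`npek` treats non-peptidic epitope prediction as a two-step problem: first
assign a molecule to a structural class, then ask how epitope-like it is
*within* that class.  The motivation is that lipids, carbohydrates and small
organic haptens are presumably recognized through different mechanisms, so a
single global classifier would mix incompatible decision rules.  Within a
class, the signal is assumed to live in counted circular substructures: the
number of occurrences of an atom environment (e.g. repeated CH₂ units of a
fatty-acid chain, repeated amide moieties of a glycan backbone) carries
information that mere presence/absence does not.

Consequently two encodings coexist deliberately:

* **clustering encoding** — folded Morgan bit fingerprints, 1024 bits,
  radius 3, non-chiral.  Folding keeps k-means tractable and the bit view is
  sufficient to separate gross structural families.
* **classifier encoding** — unfolded Morgan count fingerprints, radius 3,
  chiral.  Feature identifiers are RDKit's stable 32-bit environment
  hashes; hash collisions are accepted.  Folding maps a hash to
  `hash mod n_bits`.

## Pipeline parameters

| parameter | default | meaning / rationale |
|---|---|---|
| radius | 3 | circular environment depth; radius 0 sees only atom types, 3 captures ring/chain context |
| n_bits | 1024 | folded width for clustering |
| k (clusters) | 8 | user judgement supported by the exported inertia curve; no automatic kink detection because real curves rarely show an unambiguous elbow |
| n_init | 10 | best-of-n k-means restarts; inertia is non-increasing in n_init |
| min_occurrence | 10 | a feature must occur in ≥ 10 molecules of a cluster to be retained |
| pcc_threshold | 0.8 | greedy decorrelation: drop a feature whose \|Pearson r\| with an already-kept feature exceeds 0.8 |
| RF trees | 100 | probability = fraction of trees voting positive |
| k-NN k | 5; MLP: one hidden layer of 100 units, ≤ 200 epochs | the common library defaults, recorded explicitly for portability |
| CV | 3 repeats × 5 stratified folds | ROC-AUC averaged over the 15 fold values, sd reported |

Seeding: a single run seed is expanded through `numpy.random.SeedSequence`
into per-component seeds (splitter, estimator, shuffler), all below 2³¹, so
complete runs replay bit-identically.

## Numerical and design choices

* **Preprocessing order.**  Per cluster: encode → remove identical count
  vectors → trim by min_occurrence → prune correlated columns.  Identical-row
  removal therefore guarantees unique rows *at the stage it runs*; pruning
  columns afterwards can re-collide a few rows, which is accepted (the
  filter can be re-applied if uniqueness of the final matrix matters).
  Row removal is label-independent, so the B and T assays share one feature
  registry per cluster; when duplicate rows carry conflicting labels the
  surviving row is positive (a molecule positive in any record is positive),
  and the conflict is logged.
* **Greedy pruning order** is ascending feature id for determinism; an
  explicit ranking can be supplied (e.g. chi-squared-descending).  Pearson
  correlation is computed on raw counts, not binarized.  Zero-variance
  columns have undefined correlation; they are kept with a warning and
  treated as correlation 0.
* **Chi-squared feature test.**  Observed values are class-wise count sums;
  expected values allocate the feature's total count by each class's share
  of molecules; 1 degree of freedom for two classes.  A zero-count feature
  carries no evidence (p = 1, logged).  Bonferroni m = number of features
  surviving trimming/pruning in that cluster, applied separately per assay.
* **MISSING semantics.**  Fold-enrichment and mean count difference are
  undefined when no background molecule contains the feature; they are
  carried as an explicit null and rendered "-" in text reports.  Mean count
  difference is positives minus background, computed only over
  feature-containing molecules, so a background-heavier feature is negative.
* **Dummy null.**  Labels are permuted uniformly once per CV repeat (not per
  fold), preserving the positive fraction, then the stratified splitter and
  the RF run on the permuted labels exactly as a real model would.
* **Similarity baseline.**  Under CV a held-out molecule is scored against
  the *training-fold* positives only, so it never matches itself; outside CV
  a query identical to a stored epitope scores 1.0 by design.
* **Feature-set sweeps** re-fit the chi-squared ranking inside each training
  fold (leakage-safe).  A whole-data ranking variant is available behind a
  flag (`selection_per_fold=False`) for emulating analyses that rank once on
  the full data.
* **k-means edge cases.**  Ties in nearest-centroid assignment break toward
  the lowest index.  Empty clusters during fitting are handled by the
  underlying Lloyd implementation's re-seeding.  PCA of a zero-variance
  matrix returns all-zero coordinates and zero variance fractions instead of
  0/0.
* **Prediction input space.**  Query features absent from a cluster's
  registry are dropped and counted (`dropped_features`), so out-of-domain
  queries are visible.  Neighbor ranking uses Euclidean distance over the
  cluster's retained feature counts, while the displayed Tanimoto uses full
  unfolded fingerprints — two deliberately different spaces (model space
  vs whole-molecule similarity).  Production models use the full retained
  feature set; `top_k_features` selects a smaller chi-squared-ranked model
  for interpretability-first deployments, with its own registry stored so
  scoring always matches the fitted input space.
* **Background/positive overlap.**  When merging collections, a canonical
  SMILES present in both keeps the positive labels and the epitope source
  tag; duplicate records OR-merge their labels.  No standardization beyond
  toolkit canonicalization is applied (salts and stereo are taken as
  written).

## Synthetic data

The generator emulates the signal structure of real non-peptidic epitope
collections: diverse decorated ring scaffolds (aromatic, pyranose,
heterocyclic, phosphate-linked) carrying unbranched alkyl chains, where
positives have long chains (12–20 CH₂, vs 1–6 in the background) and/or a
planted secondary-amide motif (attachment probability 0.8).  Defaults are
300 background + 33 positive molecules (~10% positives), with 40% of
positives also T-assay positive.  The label rule (chain length ≥ 10 OR motif
present) is satisfied exactly by construction, so parameter-recovery tests
know the ground truth; `motif_feature_ids` exposes the motif's environment
hashes for rank-recovery assertions.

Presets: `separable` (noise-free chain separation), `motif_only` (identical
chain distributions, motif is the only signal), and `bit_blind` — both
classes' chains exceed 2·radius+1 carbons, so their environment *sets* are
saturated and identical while occurrence counts differ, reproducing the
core rationale for count features: bit fingerprints cannot separate the
classes, count fingerprints can.

What the generator does **not** emulate: real chemical diversity (it uses
six scaffold templates with combinatorial decorations), stereochemistry-
dependent labels, assay noise and label errors, class imbalance beyond the
configured fractions, and database-scale feature spaces (tens of molecules
× dozens of features here vs thousands × thousands in curated collections).
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted signals at desk scale, not real-data performance.

## Problem sizes

Tests and the acceptance script run on generated sets of 120–333 molecules
with clusters of 2–8, chosen as the smallest sizes at which every stage
(trimming at min_occurrence 10, stratified 5-fold CV with ≥ 5 positives per
class, stable k-means) operates in its intended regime.

## Known limitations

* Greedy PCC pruning is order-dependent; the deterministic ascending-id
  default is a convention, not an optimum.
* The chi-squared count test treats counts as frequencies in a contingency
  sense; heavy-tailed count distributions can inflate the statistic.
* Bonferroni is conservative for correlated features (they are pruned, but
  only above the 0.8 threshold).
* The CLI `benchmark` command treats its input as a single structural
  class; per-cluster benchmarking is done by clustering first and passing
  per-cluster files, or through the library API.
* No applicability-domain model beyond the dropped-feature count; a query
  far from every cluster still receives a class and a probability.
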