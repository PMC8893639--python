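# npek — non-peptidic epitope prediction from circular fingerprints

Most epitope-prediction tools handle peptides only, yet lipids,
polysaccharides, glycolipids, drugs and other small molecules are also
recognized by B cells and T cells.  `npek` is a library and command-line
tool for predicting whether a non-peptidic molecule can act as a B-cell or
T-cell epitope, for researchers in immunoinformatics and early drug/safety
assessment who have labeled molecule collections (e.g. assay-positive
structures against a chemical background) as SMILES.

## Method

The analysis is a two-step cluster-then-classify pipeline over Morgan
(ECFP-style) circular fingerprints:

1. **Structural classes.**  All molecules are encoded as folded Morgan *bit*
   fingerprints (1024 bits, radius 3, non-chiral) and partitioned with
   k-means.  The inertia (elbow) curve and a 2-component PCA projection are
   exported; the cluster count is a user judgement.
2. **Per-cluster classifiers.**  Within each cluster, molecules are encoded
   as *unfolded Morgan count* fingerprints (radius 3, chiral) — count
   features distinguish repetitive motifs such as long fatty-acid chains
   that bit fingerprints conflate.  Molecules with identical fingerprints
   are dropped, features occurring in fewer than 10 molecules are trimmed,
   and features with |Pearson r| > 0.8 to an already-kept feature are
   greedily pruned.  A 100-tree random forest (alternatives: k-NN, MLP) is
   trained per cluster and per assay (B / T) and benchmarked with repeated
   (3×) 5-fold stratified cross-validation against
   - a **count-Tanimoto baseline**: score = max over known epitopes of
     `Σᵢ min(aᵢ,bᵢ) / Σᵢ max(aᵢ,bᵢ)` (training-fold positives only under CV), and
   - a **shuffled-label null** (dummy RF): labels permuted once per CV
     repeat, preserving the positive fraction — a sound setup scores
     ROC-AUC ≈ 0.5.
3. **Interpretation.**  Each retained feature *j* is tested with a
   chi-squared statistic on class-wise count sums
   (`Σ_c (O_c − E_c)²/E_c`, `E_c = total_j × n_c/n`, 1 df), Bonferroni
   corrected per cluster × assay, and reported with its epitope coverage,
   fold-enrichment (MISSING when the background lacks the feature) and mean
   count difference among feature-containing molecules, plus the extracted
   substructure fragment.
4. **Prediction.**  A query is routed to its structural class, scored by
   that class's models, annotated with the significant substructures it
   contains, and compared to the 5 most similar known epitopes (Euclidean
   distance over the class's retained feature counts; whole-molecule
   count-Tanimoto shown alongside).

A seeded synthetic generator (`npek.generate`) emulates the dominant real
signal — long carbon chains and a planted amide motif on ring scaffolds —
so the whole pipeline is testable without any database downloads.

## Worked example

```python
import npek

# study-shaped synthetic collection: 300 background + 33 positives
ms = npek.generate(npek.SyntheticSpec(seed=0))
fm, labels = npek.build_cluster_matrix(ms.molecules, ms.labels("b"))
print(f"feature matrix: {fm.n_molecules} molecules x {fm.n_features} features")

cv = npek.CVConfig(seed=0)
for spec in (npek.ModelSpec.rf(), npek.ModelSpec.similarity(), npek.ModelSpec.dummy_rf()):
    res = npek.cross_validate(spec, fm, labels, cv)
    print(f"{spec.kind:>10}: ROC-AUC {res.mean_auc:.3f} +/- {res.sd_auc:.3f}")

stats = npek.feature_statistics(fm, labels)[0]
print(f"top feature {stats.feature_id}: corrected p {stats.corrected_p:.2e}, "
      f"coverage {100*stats.epitope_coverage:.0f}%, fold-enrichment {stats.fold_enrichment:.2f}")

tp = npek.train_pipeline(ms, k=3, seed=0)
epi = next(m for m in ms if m.label_b)
report = npek.predict(epi.smiles, tp)
print(f"query {report.query_smiles} -> cluster {report.cluster_id}, "
      f"P(B epitope) = {report.prob_b:.2f}")
```

prints

```
feature matrix: 332 molecules x 67 features
        rf: ROC-AUC 1.000 +/- 0.000
similarity: ROC-AUC 1.000 +/- 0.000
  dummy_rf: ROC-AUC 0.523 +/- 0.141
top feature 161963127: corrected p 0.00e+00, coverage 100%, fold-enrichment 4.69
query CNC(=O)CCCCCCCCCCCCCCCCCCC(C)C1CCCO1 -> cluster 0, P(B epitope) = 0.79
```

The planted signal is noise-free, so the RF and the similarity baseline
separate perfectly while the shuffled-label null stays at chance; the top
enriched feature is an environment of the planted secondary-amide motif,
present in every positive and 4.7× enriched over the background.

The same workflows are available from the shell:

```bash
npek simulate --preset separable --seed 6 --out synth.csv
npek cluster  --input synth.csv --k 8 --out run/
npek train    --background bg.csv --epitopes epi.csv --out model/
npek predict  --model model/ --smiles "CCO..."
npek stats    --model model/ --cluster 4 --assay t --top 8
npek benchmark --config bench.yaml
```

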