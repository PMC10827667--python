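# lithopredict

Transcriptomic biomarker discovery and treatment-response prediction for
bipolar disorder (BD) from lymphoblastoid cell line (LCL) RNA-seq.

More than half of BD patients do not respond to lithium, the first-line
treatment. Gene expression in patient-derived LCLs — in particular
immunoglobulin heavy- and light-chain variable genes — carries a signal
that separates lithium responders (LR) from non-responders (NR), and BD
patients from controls. Turning that signal into a predictor requires a
pipeline that survives two obstacles: batch effects that dominate the
leading principal components of multi-batch RNA-seq, and the overfitting
risk of training classifiers on ~22,000 genes with a few dozen subjects.

`lithopredict` implements that pipeline as a tested, reusable library with
a CLI, exercised entirely on a bundled synthetic-cohort generator:

1. **Simulation** (`simcohort`) — negative-binomial count studies with
   planted marker genes, per-gene batch location/scale effects,
   library-size variation, replicate samples and an immunoglobulin-like
   gene class. Presets emulate a 3-batch discovery cohort
   (10 CTRL / 9 LR / 10 NR subjects, 46 RNA samples) and a single-batch
   replication cohort from another laboratory (12 LR / 12 NR).
2. **Harmonization** (`harmonize`) — the parametric empirical-Bayes
   location/scale adjustment (ComBat model): per batch *i* and gene *g*,
   standardized data *Z* receive shrunken location and scale corrections

   γ*ᵢg = (nᵢ τ̄²ᵢ γ̂ᵢg + δ*²ᵢg Ῡᵢ)/(nᵢ τ̄²ᵢ + δ*²ᵢg),
   δ*²ᵢg = (θ̄ᵢ + ½ Σₛ (Z₉ₛ − γ*ᵢg)²)/(nᵢ/2 + λ̄ᵢ − 1),

   iterated to convergence, with method-of-moments hyperpriors (normal on
   γ, inverse-gamma on δ²). A limma-style linear residualization and a
   PC1-batch-association R² diagnostic accompany it. The implementation
   is validated against Bioconductor `sva::ComBat` in the test suite.
3. **Differential expression** (`diffexpr`) — drop genes with < 10 total
   counts, median-of-ratios size factors, two-sided Mann–Whitney U per
   gene (exact by enumeration for n ≤ 12, tie-corrected normal
   approximation otherwise), Benjamini–Hochberg FDR, and the DEG gate
   *p*-adjusted < 0.05 with |log₂FC| ≥ 1; plus the immunoglobulin-fraction
   enrichment statistic.
4. **Feature selection** (`featselect`) — Mann–Whitney screen to the k=20
   smallest p-values, exhaustive enumeration of all candidate subsets up
   to size 7 (137,979 subsets), each scored by the mean accuracy of an
   L2-logistic classifier over stratified subject-level 50/50 splits, an
   accuracy gate of 0.93, and a consensus panel of the genes appearing
   most often in passing subsets (7 genes for LR vs NR, 5 for BD vs CTRL).
5. **Classification** (`classify`) — logistic regression, random forest,
   k-NN, RBF-SVM and a small neural network, evaluated with accuracy =
   (1/n)Σ1(ŷᵢ=yᵢ), precision = tp/(tp+fp), recall = tp/(tp+fn), pooled
   confusion matrices and the rank-based ROC AUC over 50 repeated
   stratified subject-level 50/50 splits, and a cross-cohort transfer
   protocol (train on cohort 1, predict cohort 2 after covariate-free
   joint harmonization).
6. **GWAS overlap** (`gwas`) — symbol-level intersection of DEG lists
   with per-study GWAS gene sets.

## Worked example

Simulate the discovery-cohort preset and run the lithium-response
pipeline:

```sh
$ lithopredict simulate --preset cohort1 --seed 7 --out cohort1
$ lithopredict run --cohort cohort1 --task response --seed 7 --out run_out
     accuracy_mean  accuracy_sd  precision_mean  recall_mean  auc_mean  auc_sd
Lr             1.0          0.0             1.0          1.0       1.0     0.0
RF             1.0          0.0             1.0          1.0       1.0     0.0
KNN            1.0          0.0             1.0          1.0       1.0     0.0
SVM            1.0          0.0             1.0          1.0       1.0     0.0
NN             1.0          0.0             1.0          1.0       1.0     0.0
```

The table is the repeated-split evaluation of the five classifiers on the
selected 7-gene panel: mean ± sd of accuracy over 50 stratified 50/50
subject-level splits, plus mean precision, recall and ROC AUC. Perfect
scores are expected here because the simulated markers are strong
(planted |log₂FC| ≥ 1.5) and the panel recovered them. `run_out/`
contains the full artifact bundle — the DE table and DEG list, the
immunoglobulin enrichment report, the batch diagnostics
(`batch_association_before,after ≈ 0.999 → 0.037`: the PC1 batch signal
removed by the EB correction), `panel.json` with consensus frequencies
and screen p-values, and the per-repetition evaluation records — each
stamped with the seed and config hash.

The library surface mirrors the CLI, e.g.:

```python
from lithopredict import simcohort, harmonize, featselect

counts, meta, ann = simcohort.generate_cohort(simcohort.cohort1_config(seed=7))
X = harmonize.log_normalize(counts)
model = harmonize.CombatModel(X, meta["batch"]).fit()   # BatchModel results
print(model.summary())
```

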