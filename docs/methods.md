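# Methods

This note documents the models, defaults and design choices behind
`lithopredict`, in the order data flow through the pipeline.

## Synthetic count model

`simcohort` draws gene-by-sample integer counts from a negative binomial
parameterized by mean μ and dispersion α (variance μ + αμ²). For gene *g*
in sample *s* of subject *j* (group *k*, batch *b*):

    counts ~ NB( d_s · exp( a_g + ln2·L_g·1[k affected] + γ_bg + δ_bg·e_gj ), α )

- **a_g** — baseline natural-log mean, Uniform over
  `baseline_mean_log_range` (default (1, 7), i.e. mean counts from ~3 to
  ~1100, a plausible span for expressed genes in an LCL library).
- **L_g** — planted log₂ fold-change; 0 except for `n_marker_genes`
  (default 20) markers whose |L| is Uniform over `marker_log2fc_range`
  (default lower bound ≥ 1 so every marker clears the DEG gate |log₂FC| ≥ 1;
  presets use (1.5, 3)), with random sign. The multiplier applies to the
  `affected_groups` (by default every group after the first in sorted
  order, e.g. NR in an LR/NR design).
- **γ_bg** — additive per-gene batch location offset, Normal(0,
  `location_shift_sigma`). Within-lab batches default to sd 0.6, enough
  for batch to dominate PC1 of the log expression before correction, as
  multi-batch LCL studies show.
- **δ_bg** — multiplicative per-gene batch scale factor, Uniform over
  `scale_factor_range`, acting on the subject-level residual. This is
  exactly the location/scale structure the empirical-Bayes correction
  assumes, which makes the correction testable by parameter recovery
  (`generate_cohort(..., return_params=True)` exposes the planted values;
  analysis modules never read them).
- **e_gj** — subject-level biological residual, Normal(0,
  `biological_sigma`, default 0.3). This field is not part of the minimal
  count model but is required for the batch scale factor to have a
  residual to act on; it also makes replicate samples of one subject
  genuinely correlated: replicates share e_gj (and the subject's group
  and batch effects) and differ only in depth and NB sampling noise.
- **d_s** — per-sample depth factor, log-normal with sd
  `library_size_sigma` (default 0.15), so size-factor normalization is
  non-trivial.

Immunoglobulin structure: a fraction `ig_gene_fraction` (default 0.012,
matching the ~1.1–1.2 % share of highly expressed Ig genes in LCLs) of
genes is Ig-flagged; marker genes are Ig-flagged with probability
min(1, fraction × `ig_marker_enrichment`) (default enrichment 25), so DEG
lists inherit the Ig excess seen in real LR/NR comparisons.

Presets: `cohort1_config` reproduces the discovery design — 29 subjects
(10 CTRL / 9 LR / 10 NR), 46 RNA samples in 3 batches, with per-batch
duplicate counts fixed so subjects and samples tile those totals exactly.
`cohort2_config` is the
cross-laboratory replication cohort: 12 LR / 12 NR, one batch, no
replicates, and a much stronger batch effect (location sd 3.0, scale range
(0.4, 2.5)). The magnitude is a deliberate study condition: cross-lab
protocol differences (library prep, chemistry) shift individual genes by
orders of magnitude, and only a shift comparable to the marker effect
sizes makes the transfer ablation informative — with a weak shift an
uncorrected predictor can succeed by luck on a 7-gene panel. The default
gene panel is 2,000 genes for desk-scale runs; the ~22,000-gene scale is
one config field away.

What the generator does *not* emulate: read-level artifacts (GC/length
bias, mapping ambiguity), gene–gene correlation beyond the shared batch
and subject factors, outlier samples, and composition effects.  Passing
tests therefore show that the pipeline recovers structure *under its own
modeling assumptions*; they cannot certify performance on real cohorts.

## Empirical-Bayes batch harmonization

`harmonize.CombatModel` implements the parametric ComBat model. Steps:
least-squares fit of expression on batch indicators (weighted-sum-to-zero,
giving the grand mean) plus optional protected covariates; pooled residual
variance σ̂²_g (÷N); standardization Z = (X − α̂_g − covariate fit)/σ̂_g;
per-batch raw location/scale estimates (batch mean and ddof-1 variance of
Z); method-of-moments hyperpriors — Normal(Ῡᵢ, τ̄²ᵢ) on locations and
inverse-gamma(λ̄ᵢ, θ̄ᵢ) on variances with λ̄ = m²/v + 2, θ̄ = m(λ̄ − 1);
and the standard fixed-point iteration of the conditional posterior means,
stopping when the largest parameter change drops below 1e-4 (cap 100
iterations; non-convergence is recorded on the results object and the last
iterate used). The corrected value is σ̂_g (Z − γ*)/δ* + α̂_g + covariate
fit. The test suite checks this against Bioconductor `sva::ComBat` on a
shared fixture (agreement ≲ 1e-5).

Numerical guards: variances are floored at 1e-8; a gene constant across
all samples passes through unchanged; if the raw batch variances are
identical across genes the scale prior is degenerate (v = 0) and no scale
shrinkage is applied; with a single batch the model is the identity by
construction (γ̂ ≡ 0, δ̂² ≡ 1).

Covariate protection: group labels are included in the standardization
design for training data (flag on by default) so biological differences
are not absorbed into the batch means. For cross-cohort transfer the
joint correction is fitted *without* any response labels — the test
cohort's labels stay sealed; only the unlabeled test expression informs
the batch parameters. This is the defensible reading of a transfer
experiment and the residual leakage surface (test expression influencing
the correction) is inherent to joint harmonization.

`residualize_batch` (limma-style) fits sum-to-zero batch contrasts
alongside a protected design and subtracts only the batch component; it
feeds the PCA diagnostics. `batch_association` reports the R² of a
one-way ANOVA of sample PC1 scores on batch labels (0 on a constant
matrix), the number the before/after PCA plots summarize.

Input space throughout the predictor branch: log₂(count/size-factor + 1).

## Differential expression

The DE stage is intentionally a *defined simplified test*, not a
reimplementation of a negative-binomial GLM: genes with fewer than 10
total counts are dropped (exclusive threshold, total across samples — the
weakest filter consistent with the design it reproduces), counts are
normalized by median-of-ratios size factors (reference = per-gene
geometric mean over genes expressed in every sample), each gene gets a
two-sided Mann–Whitney U test, p-values are BH-adjusted, and DEGs are the
genes with adjusted p < 0.05 and |log₂FC| ≥ 1 (fold-change > 2 and
|log₂FC| ≥ 1 treated as the same gate), sorted by ascending adjusted p.
Log fold-changes use pseudocount 0.5 on the normalized group means to
avoid infinities.

The exact Mann–Whitney branch (n₁+n₂ ≤ 12) enumerates all group
assignments over pooled mid-ranks and reports
p = min(1, 2·min(P(U ≤ u), P(U ≥ u))), which is exact under ties because
the null distribution is computed on the observed tie pattern. Larger
samples use the tie-corrected normal approximation (scipy). If all pooled
values are identical the test returns p = 1.

Replicates: by default a subject's replicate samples are averaged (after
normalization) before testing, so subjects — not RNA aliquots — are the
units of inference; a flag disables the collapse for analyses that
deliberately operate at the sample level.

## Feature selection

Screen: per-gene two-sided MWU between the classes on harmonized,
subject-collapsed expression; keep the k = 20 smallest p-values (ties
broken by larger absolute median difference, then gene id). Search:
every subset of the candidates from size 1 up to `max_size` (default 7,
the largest panel used; 137,979 subsets for k = 20 — the full 2²⁰
enumeration is available by config but adds nothing beyond the panel
sizes actually selected). Each subset is scored by the mean test accuracy
of an L2-penalized logistic classifier (λ = 1, intercept unpenalized)
over 5 stratified subject-level 50/50 splits, features z-scored on the
training half; resubstitution scoring was rejected as overfit-prone. The
scorer is a Newton/IRLS fit vectorized across all subsets of one size,
which keeps the full enumeration to seconds on one CPU; a test pins its
accuracies to sklearn's LogisticRegression on identical splits. Gate:
subsets with accuracy strictly above `accuracy_threshold` (default 0.93)
pass. Consensus: genes ranked by their frequency among passing subsets
("constantly appeared" formalized as highest appearance frequency), ties
broken by screen p then gene id; the top 7 (response) or 5 (diagnosis)
genes form the panel. The gate applies globally across subset sizes. An
empty passing set raises a `GateError` naming the threshold knob — the
expected outcome on null data.

## Classification and evaluation

Five classifiers with fixed documented defaults (hyperparameters were not
tuned): logistic regression (C = 1), random forest (100 trees), k-NN
(k = 5), RBF-SVM (C = 1, scores from the decision function so no
probability calibration randomness), and a one-hidden-layer neural
network (16 rectified units, ≤ 500 epochs, seeded init). Metrics follow
their textbook definitions; zero-denominator precision/recall report 0
with the zero visible in the confusion matrix. AUC is the tie-aware
rank-sum identity (probability a random positive outscores a random
negative, ties ½), cross-checked in tests against the Mann–Whitney U
statistic and sklearn.

Repeated evaluation draws 50 stratified 50/50 splits at the *subject*
level (all samples of a subject on one side; a split missing a class is
redrawn), standardizes features on the training half, and reports per
repetition plus aggregates: mean ± sd accuracy and AUC, pooled confusion
matrix, pooled-score ROC points. The positive class is NR for the
response task and BD for the diagnosis task.

Cross-cohort transfer: both cohorts are jointly log-normalized and
EB-harmonized with cohort as the batch and no covariates, classifiers are
trained on cohort 1's subject-collapsed panel profiles only, and a single
prediction pass over cohort 2 is scored against the held-out labels.
`harmonize=False` gives the ablation. Note that linear classifiers
extrapolate through random per-gene shifts and can survive the ablation
by chance; kernel- and distance-based classifiers (SVM, k-NN, NN) expose
the need for harmonization much more reliably, which is why the
transfer checks lean on the SVM.

## Determinism and problem sizes

Every stochastic step takes a seed and uses an isolated
`numpy.random.Generator`; identical seeds give byte-identical artifacts
(JSON reports carry the seed and a config hash). The bundled checks run
at desk scale — 2,000 genes, 20 markers, 20-subject classes, subset sizes
≤ 5 for the multi-seed recovery studies — sizes chosen so the full
enumeration and 50-repetition evaluations complete in minutes while
leaving the statistical questions (screen recovery, consensus stability,
FDR calibration, transfer ablation) intact. The full-study defaults
(~22,000 genes, gate 0.93, sizes ≤ 7) remain the library defaults.

## Known limitations

- The DE stage trades the power of moderated NB models for full
  specifiability; at 19 subjects its rank test is conservative, so DEG
  counts on small cohorts undershoot what a GLM with dispersion shrinkage
  would report.
- Consensus frequencies are nearly flat when almost all subsets pass the
  gate (strong markers); the panel is then effectively chosen by the
  screen ordering, which the tie-break makes explicit and deterministic.
- Joint harmonization of train and test cohorts uses unlabeled test
  expression; fully prospective correction (frozen parameters applied to
  one new sample at a time) is out of scope.
- The non-parametric ComBat variant, surrogate-variable methods and
  reference-free batch inference are out of scope.
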