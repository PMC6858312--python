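# Methods

## Problem and model

`oncotyper` classifies a tumor sample's cancer type from the somatic
alterations detected in its genome. The premise is that alteration patterns
are strongly tissue-specific: which genes are recurrently mutated, how heavy
the mutation burden is, which base-substitution processes dominated, and
which genomic regions gained or lost copies all vary systematically by
cancer type. The pipeline has three stages:

1. **Featurization.** Each sample becomes one row of a fixed-schema matrix
   with five blocks, concatenated in this order:
   - *mutation profile* — integer counts of protein-altering SNVs and indels
     per gene (G_m columns);
   - *mutation rates* — (SNVs+indels)/Mb of sequenced territory, and the
     fraction of schema genes carrying at least one variant (2 columns);
   - *mutation spectra* — proportions of SNVs in the six pyrimidine-referenced
     substitution classes C>A, C>G, C>T, T>A, T>C, T>G (6 columns);
   - *mutation signatures* — proportions over the 96 trinucleotide-context
     classes {A,C,G,T} × spectrum × {A,C,G,T}, keys like `CCT.C>T`
     (96 columns);
   - *SCNA* — gene-level log2 tumor/normal copy ratios (G_c columns,
     prefixed `cnv:` to keep names globally unique).

   The total dimension is always G_m + 2 + 6 + 96 + G_c. Purine-referenced
   SNVs are folded into the pyrimidine frame by complementing ref/alt and
   swap-complementing the flanks, which makes the spectrum and signature
   blocks invariant to the reported strand. Indels carry no substitution
   context and contribute only to the profile and rate blocks. SNVs with an
   unknown ('N') flank are excluded from the signature block entirely
   (numerator and denominator) but still count toward profiles, rates and
   spectra.

2. **Supervised feature selection.** The matrix is sparse and mostly
   uninformative, so it is cut to roughly 10–20% of its columns before
   classification. Three selectors are implemented behind one interface:
   extremely-randomized-trees impurity importance (top-k), LASSO
   (one regression per one-hot-encoded class, objective
   (1/n)·Σ‖y_i − wᵀx_i‖² + α‖w‖₁, union of supports), and an L1-penalized
   squared-hinge one-vs-rest linear classifier ("LSVC", the default). The
   LSVC loss for a sample is Σ_{c≠y} max(0, 1 + f_c(x) − f_y(x))² with
   f_c(x) = w_cᵀx + b_c; the L1 budget constraint Σ_c‖w_c‖₁ ≤ ε is
   implemented in its penalized Lagrangian form with inverse weight C
   (larger C ⇔ looser budget ⇔ more features), which is the standard solver
   parameterization and maps monotonically onto ε. A bisection controller
   searches log-regularization space (bracket 1e−4..1e4, ≤40 probes) until
   the surviving-feature count lands within k·(1±tol); persistent overshoot
   is resolved by truncating the nonzero set to exactly k by |coefficient|,
   ties to the lower feature index.

3. **Classification.** A soft-voting ensemble of a multilayer perceptron and
   a random forest: each member returns per-class probability rows, the
   ensemble averages them and predicts the argmax (ties to the lowest class
   index). One-vs-rest linear SVM (probabilities via softmax over decision
   scores; Platt scaling behind a flag) and k-NN (vote fractions) are
   available as comparison members for the agreement analysis.

Evaluation is nested 10-fold cross-validation: the inner folds (run only on
outer-training rows) choose the selector and feature count by mean inner
accuracy (ties → smaller k, then method order lsvc, lasso, extra_trees); the
chosen configuration is refit on the whole outer-training set and scored on
the untouched outer fold. A runtime leakage guard SHA-1-hashes every
outer-test row and aborts if any such row reaches standardization, selection
or training within its own fold.

## Key parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `territory_mb` | 38.0 | Denominator of the per-Mb mutation rate; a typical exome footprint. Configurable because the callable territory depends on the capture kit. |
| protein-altering classes | missense, nonsense, nonstop, splice-site, frame-shift ins/del, in-frame ins/del, translation-start | Variant classifications counted as protein-altering; configurable per reader call. |
| `MlpConfig` | 3×2048 units, dropout 0.4, Adam lr 1e−5, batch 128, ≤200 epochs, patience 10, val. fraction 0.1 | Full-scale architecture defaults. Reduced configurations (2×128–256 units, lr 1e−3, ≤60–80 epochs) are used in tests and the reproduction script, where cohorts are ~100× smaller. |
| `RandomForestConfig.n_trees` | 500 | Forest size; 200–300 in reduced runs. |
| SVM / kNN | C=1, k=5 | Comparison members only. |
| `k_grid` | 5/10/15/20% of d | Candidate feature counts for the inner loop; the informative range for this family of problems sits near 10–20%. |
| `tolerance_frac` | 0.05 | Accepted relative deviation of the selected-feature count from k. |

Standardization (zero mean, unit variance, training rows only) is applied
before the L1 selectors because they are scale-sensitive; the tree selector
sees raw values, where monotone rescaling is irrelevant.

## Synthetic cohorts

`simulate_cohort` generates labeled cohorts with planted, recoverable
type-specific signal and no external inputs:

- per-sample SNV count ~ lognormal(log background rate, σ), at least 1;
- each SNV falls in one of its type's disjoint driver genes with probability
  `driver_mutation_prob` (0.35 tiny, 0.5 desk — the hallmark-driver regime:
  with ~60 SNVs per sample, virtually every sample carries its type's
  drivers, the way BRAF marks melanoma or VHL clear-cell kidney cancer),
  else uniformly in the gene universe. Drivers are deliberately the
  strongest planted signal, matching the premise that recurrently mutated
  genes are the leading type markers;
- each SNV's trinucleotide context is drawn from the type's 96-dim signature
  vector, itself a Dirichlet(α·1₉₆) draw — small α gives spiky,
  type-distinct signatures whose dominant contexts (smallest set covering
  80% of mass) are recorded as planted truth; contexts are written on the
  variant records so featurization needs no FASTA;
- ~10% of the SNV count is added as frame-shift indels without context;
- the copy-number matrix is N(0, 0.1) noise plus N(0.5, 0.35) shifts on each
  type's disjoint planted gene set — informative but noisy, as gene-level
  log2 ratios are in practice.

Two canned scales: `tiny` (3 types × 30 samples, 200+100 genes, 404
features) for unit-level work, and `desk` (6 types × 200 samples,
2,000+1,000 genes, 3,104 features) for full evaluation runs. Both are fully
seeded; identical config + seed reproduces the cohort exactly.

What the simulator deliberately does **not** emulate: real per-type burden
distributions (pediatric-to-lung dynamic range), mutational-signature
mixtures shared across types, gene-length and replication-timing effects on
background mutation rates, segment-level CNA structure (the matrix is
per-gene i.i.d.), subclonality, and germline contamination. Passing the
planted-recovery and accuracy checks therefore demonstrates that the
pipeline's machinery is correct and leak-free — not that the measured
accuracies transfer to real tumor cohorts, where class signal is far weaker
and feature correlations far stronger.

## Numerical choices

- LASSO is solved with coordinate descent; the package's α follows the
  (1/n)-scaled objective above, so the solver's parameter is α/2. α = 0
  falls back to ordinary least squares.
- The LSVC one-vs-rest fit uses liblinear (L1, squared hinge, dual=False).
  `lsvc_objective` exposes the multiclass competing-margin loss as a pure
  function so small instances can be checked against brute-force lattice
  minimization.
- Bisection over regularization is geometric (midpoint √(lo·hi)); the probe
  path is recorded on the result so sparsity monotonicity can be asserted.
- The MLP is implemented directly on numpy: He initialization, ReLU,
  inverted dropout on hidden layers (training only), softmax cross-entropy,
  Adam (β₁=0.9, β₂=0.999), stratified validation split, early stopping with
  best-epoch weight restoration. Given a seed the whole trajectory is
  bit-reproducible, which the test suite exploits.
- Spectrum/signature rows of samples with no eligible SNVs are all-zero
  rather than NaN. Missing copy-number genes or samples are zero-filled
  (log2 0 = copy-neutral), with a strict mode that errors instead.
- Stratified folds deal each class's shuffled members to the currently
  smallest fold, guaranteeing fold sizes within 1 and spreading a class with
  fewer members than folds across distinct folds.
- Per-class "accuracy" is reported as fold-averaged within-class recall when
  fold structure is available, alongside pooled recall — the two diverge
  when folds are unbalanced, so both candidate definitions are emitted.
- All displayed percentages are rounded to 2 decimals; comparisons and the
  stored values keep full precision.

## Design choices that were genuinely open

- **Multiclass LASSO encoding.** Eq.-style LASSO has a scalar target;
  multiclass labels are one-hot encoded with one regression per class and
  the union of supports taken. Alternatives (single integer coding,
  multi-task group LASSO) either impose an artificial class order or change
  the sparsity structure.
- **Ensemble membership per fold.** One MLP/forest pair is trained per outer
  fold on the inner-loop-chosen features; members are not retrained per
  inner fold for the final model.
- **Inner-loop search space.** The selector method can be searched alongside
  k (`methods` argument), but the default searches k only with LSVC fixed,
  which is the configuration the comparison analysis favors.
- **"2048 parameters" per hidden layer** is read as 2048 units; a literal
  parameter count of 2048 is inconsistent with a 35,565-input layer.
- **Agreement analysis inputs** are boolean correctness vectors, so the
  inclusion–exclusion identities hold exactly by construction at full
  precision; rounding happens only at display.

## Problem sizes used in the shipped runs

Tests and the reproduction script run the `desk` cohort (1,200 samples,
3,104 features) with the reduced MLP (2×128, lr 1e−3, ≤60 epochs), a
200-tree forest, a single-candidate inner grid (LSVC at k = 10%·d) for the
headline nested-CV number, and 10 outer folds. These sizes keep a full
reproduction run in the tens of minutes on one CPU while leaving the planted
signal comfortably recoverable; every component also accepts the full-scale
defaults.

## Known limitations

- No VCF ingestion, variant calling, liftover, or cohort download; inputs
  are MAF-style tables, SEG/BED or gene-level matrices.
- No mutational-signature deconvolution (NMF) — the 96-context block is raw
  proportions, not exposure estimates.
- Continuous log2 copy ratios only; GISTIC-style thresholded calls are not
  modeled.
- The numpy MLP is CPU-only and single-threaded; at the full 3×2048 scale it
  is slow, and users with large cohorts will want fewer units or a GPU
  framework behind the same `ProbabilisticClassifier` contract.
- Absolute accuracies on real consortium cohorts are out of scope here; the
  synthetic cohort validates mechanism, not clinical performance.
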