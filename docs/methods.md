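# Methods

## Measurement model and simulator

The generator assumes each omics layer measures a linear distortion of true
log2 abundance. For feature *g* in sample *s* of batch *b*:

    log2 I(g, s) = a(g, b) + β(b) · log2 C(g, donor(s)) + ε,   ε ~ N(0, σ_ε²)

- **a(g, b)** — additive per-feature per-batch offset, drawn
  N(0, σ_batch²). Defaults: σ_batch = 1.0 (transcriptomics, proteomics),
  1.5 (metabolomics, where batch effects run highest among the layers).
- **β(b)** — per-batch gain, default 1 (pure additive regime; gains can be
  drawn log-normally via `gain_log2_sd`). With β ≡ 1, subtracting the
  in-batch reference profile cancels a(g, b) *exactly*, which is what makes
  the exactness invariant testable; drawn gains leave a residual that
  scales with between-donor abundance differences.
- **σ_ε** — replicate noise on the log2 scale, default 0.2.

Donor structure: the anchor donor carries a baseline profile
(log2 abundance ~ N(3, 2²); metabolomics N(6, 2²) to sit above its
detection threshold). Each non-twin donor shifts a `de_fraction` (default
0.10) subset of features by signed draws from the effect-size distribution
(default magnitude Uniform(1, 3) log2 units); the twin copies its sibling's
profile except on a 2% divergence fraction. True up/down/non labels are
derived from realized pairwise log2 fold changes at an effect floor of 1
log2 unit. Fold changes between donors are therefore transitive by
construction, which a per-pair shift scheme would not guarantee.

Layer realism:

- *Transcriptomics*: intensities are exponentiated to expected counts
  (interpreting log2 C as log2 CPM at a 10⁶ library size) and rounded.
  Rounding is deterministic by default so that the identity measurement
  model reproduces replicates exactly; Poisson sampling is available via
  `count_noise="poisson"` when count-level stochasticity matters.
- *Proteomics / metabolomics*: intensities stay on the normalized-abundance
  scale and are masked missing-not-at-random with probability
  `sigmoid(miss_intercept + miss_slope · (−log2 I))`, so low-abundance
  analytes vanish preferentially (defaults −2.0/1.0 and −2.0/0.5,
  giving a few percent overall missingness concentrated at the low end).

What the generator does **not** emulate: gene-length/GC bias, count
overdispersion beyond Poisson, correlated features (co-expression),
platform-specific missingness mechanisms, or lab-to-lab protocol
differences beyond the linear batch term. Passing tests therefore
demonstrate that each method behaves as its design predicts *under the
linear batch model*, not that it will rank identically on any real
dataset — in particular, the balanced-scenario ARI of 1 reflects the strong,
well-separated donor signal the defaults encode.

### Reference-quality degradation

Two degradation modes mimic low-quality reference samples:

1. **Noise injection** (`inject_reference_noise`): per feature per batch,
   zero-mean normal noise with SD = `fold_sd` × the per-feature SD of that
   batch's reference replicates is *added* to each reference replicate.
   Read literally, the source procedure "randomly generates" the modified
   values with mean zero, which would replace the reference with pure
   noise and discard its signal entirely; the additive reading is the one
   under which a fold of 0 is the identity and small folds degrade
   gracefully. A `replace=True` switch implements the literal reading.
2. **Count degradation** (`degrade_reference_counts`): per reference
   replicate independently, a random `pct_genes` fraction of features has
   counts multiplied by 1/2, 1/4, or 1/8 (gene-specific RNA degradation);
   affected gene sets differ across replicates of the same batch.

## Preprocessing conventions

Counts → CPM; floors of 0.01 (transcriptomics, proteomics) or 1
(metabolomics) added before log2. Missing values are imputed with zero for
the native corrections, or with N(0, sd²) jitter (sd 0.01, metabolomics 1;
negative draws kept, no truncation) for plugged-in methods that cannot
tolerate within-batch constant features. Detection requires a value ≥ 0.1
in strictly more than 30% of libraries (metabolomics: ≥ 1 in > 70%) —
"over" is read as a strict inequality — computed on the un-imputed
normalized matrix and intersected across the scenario subsets. Detection
order relative to imputation is not fixed by the source conventions; we
filter before imputing so that imputed zeros cannot create detections.

## Corrections

- **raw** — identity.
- **bmc** — subtract each feature's within-batch mean over all samples the
  method sees.
- **ratio** — subtract the arithmetic mean of the log2 profiles of
  `n_ref_replicates` (default 3) in-batch reference replicates (the
  geometric mean on the linear scale); output scale `ratio_log2`. When
  fewer replicates than available are requested, the subset is drawn once
  per batch with the scenario seed. Reference samples are corrected by the
  same denominator and retained for diagnostics, but excluded from every
  metric.

The evaluation hands the reference replicates **only to reference-based
corrections** (`uses_reference=True` in the registry). This mirrors
practice — a method that ignores reference samples would not carry them —
and it is load-bearing for the confounded scenario: if BMC were centered on
batches that contain reference replicates, the reference donor would anchor
every batch mean and BMC would inherit the reference method's robustness.
With study samples only, centering a single-donor batch subtracts the
donor's own mean profile, which is the signal-destruction mechanism the
confounded scenario exists to expose.

External methods (ComBat, Harmony, SVA, RUVg/RUVs, …) are adapter slots via
`register_beca(name, fn, imputation, uses_reference)`; the registry enforces
the shape contract and records the declared imputation need.

## Differential expression and consensus truth

Within each batch, log2 FC = difference of replicate means; p from a
two-sample t-test on the replicates (pooled-variance Student by default, as
in the source workflow; Welch available). Zero-variance groups get a pooled
variance floor of 1e-12, so identical groups yield t = 0, p = 1. DEF calls:
up if p < 0.05 and FC > 2 (metabolomics 1.5), down if FC below the
reciprocal, else non; an optional Benjamini–Hochberg gate replaces the raw
p threshold without changing the pipeline topology.

Consensus truth is built from the *uncorrected* full-design log2 data:
reference FC = mean of the intra-batch FCs across all 15 batches, retained
when p < 0.05 in at least 3 batches; reference labels by plurality vote over
the 15 per-batch calls, with tied pluralities excluded (the printed
exclusion rule is ambiguous as stated; tie-of-plurality exclusion is the
reading implemented). Cross-batch comparisons draw 3-vs-3 selections
(balanced: one replicate per donor from each of 3 random batches;
confounded: all 3 replicates from one random batch per donor), 15 repeats ×
3 donor pairs per scenario, using study samples only.

## Metrics

- **SNR**: PCA after per-feature centering and unit-variance scaling
  (constant features dropped); decibel ratio of mean weighted squared
  between-donor to within-donor score distances in PC1–PC2, weights = the
  components' variance fractions. Unequal replicate counts use per-donor
  pair counts in the prefactor (the combinatorial form reduces to
  m·C(n,2)/(C(m,2)·n·n) at equal n). Zero within-spread returns +inf with a
  warning.
- **Confusion of DEF calls**: positives are reference up/down features; a
  call is TP only when its direction matches; a reference-positive called
  in the wrong direction counts as FP (a spurious directional claim), which
  keeps TP+TN+FP+FN equal to the evaluated feature count.
- **MCC** with the standard 0-when-any-marginal-is-0 convention; Jaccard of
  DEF sets (1 when both empty); sensitivity/specificity/precision/F1 from
  the same counts.
- **RC**: Pearson r over the intersection of test and retained reference
  features (≥ 3 required).
- **ARI**: the standard chance-adjusted pair-counting index. (The printed
  source formula `(RI + E(RI))/(max(RI) − E(RI))` carries a sign error; the
  standard definition is implemented and cross-checked against a
  brute-force all-pairs oracle.)
- **Total score**: per metric min–max scaling to (0,1) across corrections,
  then the mean of SNR, MCC of DEFs, prediction MCC, and ARI; a constant
  metric column scales to 0.5 for every method so it cannot break ties
  arbitrarily.

## Prediction and integration

Endpoints are donor-inherited binary labels (sex: F7 male vs D5/M8 female;
age: twin daughters young vs parents old). Samples from the first 9 batches
by processing order form the training set (27 of 45 study samples), the
rest validation (18). Models are selected by mean MCC over 25 runs of
stratified 5-fold CV and refit on the full training set. The named
machine-learning algorithms of the source workflow are replaced by a
classifier plugin contract with two native baselines (nearest centroid —
the default, hyperparameter-free and fast — and L2 logistic regression with
a small C grid); the two-layer validation harness is the object under test,
not any particular learner. If a confounded chronological split leaves a
training class with fewer than two samples, that endpoint is skipped rather
than scored degenerately.

Integration selects 36 study samples from 12 batches per repeat (batch
draws stratified per donor when batches are donor-exclusive, so every layer
contributes 12 samples per donor), aligns layers positionally within donor
after sorting by (donor, batch order, replicate) — balanced replicate
choices and confounded batch assignments are made independently per layer,
so no cross-layer sample-id correspondence exists to align on — then
standardizes features per layer. The native clustering concatenates layer
blocks and runs spectral clustering (k-nearest-neighbor affinity, k = 3
groups); a native similarity-network-fusion method (scaled exponential
kernel, 12 neighbors, hyperparameter 0.5, 10 cross-diffusion iterations) is
provided under `method="snf"` with the same contract. ARI is computed
against donor labels.

## Seeds and problem sizes

A master seed fans out through named `SeedSequence` sub-streams
(simulation / scenario / DE sampling / CV folds / integration), so each
stage is independently reproducible and any reported number is recomputable
from config + seed alone. Study-condition defaults: 2000 features per
layer, 15 batches × 4 donors × 3 replicates, 15 DE repeats, 10 integration
repeats, 25×5 CV. The test suite exercises directional claims at reduced
sizes (200–500 features, 2–5 repeats) chosen as the smallest problems at
which the effects are unambiguous across seeds; the acceptance script runs
the clustering evaluation at the full 2000 features.

## Known limitations

- Only the additive-gain regime (β ≡ 1) is exercised by default; with
  per-batch gains, ratio scaling corrects offsets exactly but gains only up
  to the reference-to-study abundance difference.
- The confounded scenario assigns equal-size batch groups; unequal or
  partially confounded designs are out of scope.
- One reference donor per design; multi-reference designs are not modeled.
- Native re-implementations of ComBat/Harmony/SVA/RUV are deliberately out
  of scope — they enter only through the plugin contract.
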