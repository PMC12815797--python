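# Methods

This note documents the models, defaults, and numerical conventions
implemented in `tregstrat`, and what the synthetic test bed does and
does not demonstrate.

## Synthetic multi-omics generator

The generator plants a known cluster structure so that recovery can be
scored against truth. The model is deliberately the simplest one under
which consensus clustering provably works:

* `n_clusters` latent groups are assigned to samples (balanced, shuffled)
  and **shared across all layers** — the layers are coupled only through
  the labels, plus an optional shared background factor
  (`background_corr`, default 0) since real inter-layer correlation
  strength is not well characterized.
* Each layer starts as i.i.d. standard normal values. A random subset of
  features (`frac_informative`, default 0.2) receives additive
  per-cluster means drawn as `cluster_sep × N(0,1)` (default
  `cluster_sep = 3` SD units), i.e. expected pairwise cluster separation
  of √2 · 3 SD per informative feature.
* One designated cluster (default cluster 0) additionally over-expresses
  the 9-gene Treg signature, the 6-marker exhaustion panel, and two
  25-gene immune programs in the mRNA layer by `treg_effect` SD units
  (default 2). The spike magnitude varies per sample (log-normal,
  CV 0.3, mean 1) because Treg burden varies between tumors; this
  per-sample intensity is what couples the Treg signature to the
  exhaustion panel *within* the spiked cluster and lets the
  exhaustion-correlation analysis find it.
* Values are pushed through monotone transforms into each layer's
  domain: `exp(x/2)` for counts-like layers (positive, right-skewed),
  a logistic squash for methylation-style beta values in (0, 1),
  identity for continuous (protein-like) layers. Monotone maps preserve
  the planted ordering, so signal survives normalization.
* Missing entries (NaN) are injected uniformly at random, exactly
  `round(rate × n_entries)` of them. The missing sentinel is always NaN,
  never a coded number, to avoid imputation bias.
* Default sizes are 300 samples and 500/150/400/120 features for
  mRNA/miRNA/methylation/protein. These are desk-scale stand-ins for
  cohort matrices; dimensionality can be raised freely (the joint-width
  check in the tests uses full-size layers).

The generator does **not** emulate batch structure, library-size
effects, count noise models, mutation/CNV landscapes, or realistic
gene–gene correlation. Consequently, a passing recovery test shows the
pipeline machinery is correct under the stated signal model — not that
real cohorts of a given size are separable.

Tumor-growth studies are exponential:
`V(t) = V0 · exp(rate · effect · t) · ε`, with multiplicative log-normal
measurement noise of CV `noise_cv` (default 0.10, a typical caliper
repeatability) and mean 1, so `noise_cv = 0` gives the exact closed
form. Baselines are N(96.45, 12.93²) mm³ and animals are block
randomized to arms by baseline size. The default growth rate 0.2114/day
takes a ~96 mm³ tumor to ~1860 mm³ by day 14; the default arm effect
multipliers (1.051, 0.999, 0.907) are back-calculated from the reported
day-14 TGIs of the motivating study (−17.3%, +0.7%, +25.4%), so the
simulated study reproduces that efficacy pattern in expectation.

## Preprocessing

Order of operations: intersect → missingness filter → KNN imputation →
normalization → top-variance selection → concatenation. The order of
imputation vs selection is not canonical in the literature; filtering
and imputing first makes the variance ranking well defined.

* Sample intersection keeps the lexicographically sorted common ids, so
  results do not depend on input file order.
* "Excessive missingness" defaults to a feature missing fraction > 0.2
  (inclusive keep at exactly 0.2), a common omics QC convention;
  configurable.
* KNN imputation (k = 5) works in **sample space**: the distance
  between two samples is the Euclidean distance over features observed
  in both; a missing entry is the mean of its feature over the k nearest
  candidates that observe it. This plain pairwise-complete distance is
  implemented in-repo (library imputers rescale by the fraction of
  observed features, which can reorder neighbors). The implementation is
  verified against an exhaustive double-loop oracle.
* Min–max normalization is per feature; constant features map to 0
  (divide-by-zero guard). Methylation (native beta values) and protein
  (pre-normalized) layers skip min–max by default.
* Top-variance selection uses sample variance (ddof = 1); ties break by
  original feature order; surviving features keep their original
  relative order. Variance is computed on the post-normalization scale
  for normalized layers so "highly variable" is comparable across
  features.
* Concatenation prefixes feature ids with the layer name; with the
  default retention counts (2000 + 482 + 2000 + 217) the joint width is
  4699.

## Autoencoder

A compact fully connected autoencoder written on numpy: encoder widths
`input → hidden_dims` (default [4000, 1500, 800, 400]; the last entry is
the bottleneck), decoder mirrored, ReLU on hidden layers, **identity
output** (inputs mix [0,1]-scaled and unscaled values, so a squashing
output would bias reconstruction), MSE loss, Adam (lr 1e-3, β 0.9/0.999),
batch size 32 (clamped with a warning if larger than the training set),
up to 200 epochs. The data are split 90/10 train/validation
(unstratified) by the config seed; training stops when validation MSE
fails to strictly improve for `patience` = 5 consecutive epochs, and the
best-validation weights are restored. Weight init is fan-in-scaled
normal; the split, the init, and the per-epoch minibatch shuffle all
draw from one seeded generator, so fit → transform is bit-reproducible.

The default hidden widths suit a ~4700-wide joint matrix; the pipeline
config uses [256, 64] for the synthetic-scale matrices. The PCA embedder
(top-d axes, each axis's largest-magnitude loading forced positive) is a
deterministic substitute used to test the clustering stages
independently of autoencoder idiosyncrasies; the test suite requires the
planted structure to be recovered through **both** paths.

## Consensus clustering and PAC

For each K in 3…10: `n_reps` replicates (1000 by default; the pipeline
default is 100, which the recovery experiments show is ample at these
sample sizes) each draw ⌊0.8·n⌋ samples without replacement and run
K-means (k-means++ init, 1 restart, 300 iterations, tol 1e-4, a
replicate-specific seed — replicate diversity comes from subsampling,
not restarts). Consensus_ij = co-clustered / co-sampled counts; pairs
never co-sampled get 0 with a coverage warning (vanishingly rare at the
default settings but defined behavior). The diagonal is 1.

PAC is the fraction of upper-triangular off-diagonal consensus values in
the **open-left/closed-right** interval (0.1, 0.9]; lower is more
stable; the scanned K with the lowest PAC is selected, ties to the
smaller K. Because the final partition must come from the consensus
evidence rather than any single K-means run, final labels are obtained
by average-linkage hierarchical clustering of 1 − consensus cut at K
(the standard consensus-clustering convention), renumbered so cluster 1
is the largest. Silhouette scores (Euclidean; singletons scored 0) are
reported for cluster-quality summaries.

## Characterization statistics

* **Signature score**: per-gene z-score across samples (SD guard: a
  zero-variance gene contributes 0), averaged over the set's present
  genes; absent genes are warned about, never scored. A rank-based
  single-sample alternative (`ssgsea_like`, rank-weighted running sum
  with exponent 0.75) is available behind a flag. Immune/stromal-style
  scores are exactly this signature score over user-supplied sets — a
  deliberately generic scorer, not a reimplementation of any published
  deconvolution method's coefficients — and are labeled
  `immune_like_score` accordingly.
* **Gene ranking**: one-vs-rest signal-to-noise
  (μ₁−μ₀)/(σ₁+σ₀) with each σ floored at max(0.2·|μ|, 1e-8) (the
  classical GSEA convention), or log2 fold change of group means.
  Descending sort with lexicographic gene-id tie-break makes ranked
  lists deterministic.
* **GSEA**: weighted KS running sum — hit increments ∝ |score|^weight
  normalized to sum 1 (weight 1 by default), miss decrements 1/(N−N_h);
  ES is the extremum. The null permutes **set membership** (not
  phenotype labels): with varying cluster sizes and a shared embedding,
  membership permutation is the comparable, cheap null; this diverges
  from phenotype-permuted NES and is documented as such. NES = ES /
  mean |null ES| of matching sign; p is the matching-sign tail
  probability with add-one smoothing (so p ∈ (0,1]); BH FDR is applied
  across the sets of one call.
* **ORA**: hypergeometric upper tail P(overlap ≥ observed), BH across
  sets. Verified against exhaustive enumeration on small universes.
* **Group tests**: tie-corrected Kruskal–Wallis (all-identical input is
  defined as H = 0, p = 1), Dunn's post-hoc z on mean ranks with tie
  correction (Bonferroni by default, BH available), and pairwise
  Mann–Whitney/Wilcoxon rank-sum (exact for small untied samples,
  normal approximation otherwise).
* **Exhaustion panel**: per-cluster Spearman correlation between the
  Treg signature score and a mean-z exhaustion score over the marker
  panel, plus per-marker cluster means; constant vectors are flagged and
  reported as ρ = 0.
* A generic volcano filter (adjusted p < 0.05, |log2FC| > 1) is provided
  for externally fitted differential-expression tables; the DE fit
  itself is out of scope.

## Treg-cluster selection

Five criteria — count of Treg-related sets passing ORA FDR < 0.05,
pathway NES, Treg-signature GSEA NES, Treg fraction (any per-sample
abundance proxy; the pipeline uses the signature score), immune score —
are ranked per cluster (rank 1 = most Treg-like; ties share the minimum
rank). Published comparative tables state per-criterion winners but no
aggregation rule, so the package uses majority-of-rank-1 with a
deterministic cascade: lowest mean rank, then highest Treg-signature
NES, then smallest cluster id. Interval-valued table entries (e.g.
"0.05–0.07") are ingested as midpoints; raw per-sample values are
preferred when available. Selection is invariant to criterion order and
cluster relabeling.

## Efficacy metrics

* TGI at day d defaults to the **delta** form
  100·(1 − (T_d−T_0)/(C_d−C_0)) on arm mean curves (the ratio form
  100·(1 − T_d/C_d) is available and every report records which was
  used; published approximate volumes cannot disambiguate the two).
  The delta form errors if the control arm did not grow.
* Normalized AUC: per animal, trapezoidal AUC of V(t)/V(0) over 0–14 d;
  arm mean divided by control mean, so control ≡ 1 and values straddle 1
  for near-inactive arms — the scale on which the motivating study's
  monotherapy values (0.996–1.089) are expressed.
* Bliss: effect fractions f = TGI/100 with negative fractions retained
  (clipping would destroy the reported arithmetic); expected =
  f_A + f_B − f_A·f_B; exceedance = f_combo − expected. HSA excess =
  min(mono endpoint mean volumes) − combination endpoint mean volume,
  in mm³. The endpoint day defaults to the last day measured in all
  arms.
* Two-way ANOVA on endpoint volumes uses type-II sums of squares (equal
  to type-I/III on the balanced 2×2 design), each cell requiring ≥ 2
  observations.
* The randomization check reports per-arm and pooled baseline mean ± SD
  and flags arms deviating from the pooled mean by more than one pooled
  SD.

## Orchestration and reproducibility

`run_pipeline` executes synthetic → preprocess → embed → consensus →
characterize → select → efficacy, writing TSV/CSV/JSON artifacts and a
manifest with SHA-256 checksums and per-stage wall time. Stage seeds
derive from the global seed as `seed + stage_index + stage_config_seed`,
so identical configs re-run bit-identically while changing one stage's
seed moves only that stage's (and downstream) artifacts.
`validate_external_cohort` applies the same embed → cluster →
characterize path to a single expression matrix with K fixed at 3 by
default (a `rescan_k` flag re-runs the PAC scan), warns and uses all
genes when fewer than the requested retention are available, and raises
a named error when the Treg signature has no overlap with the matrix.
Cross-cohort cluster correspondence is reported as per-cluster Treg
evidence, not as a formal label-matching test.

## Problem sizes used in the test suite

Recovery and selection experiments run at 300 samples × ~1200 joint
features, consensus at 50–100 replicates, GSEA at 200 permutations, and
the autoencoder at [256, 64] widths — sizes chosen so the planted-signal
experiments are statistically decisive while the full suite stays quick
to iterate on. The unit oracles (imputation, ORA, GSEA enumeration,
silhouette, ANOVA) run at ≤ 12 samples/genes where exhaustive
computation is exact.

## Known limitations

* The membership-permutation GSEA null and the generic signature scorer
  are stand-ins for phenotype-permuted GSEA and published deconvolution
  panels; absolute NES/score magnitudes are not comparable to those
  tools, though cluster rankings are.
* Cohort-scale quantities (discovery-cohort PAC values, cohort
  silhouette ranges, differential-expression gene counts, real-data
  criterion magnitudes, absolute in vivo volumes) depend on external
  data and are not reproduced; the package demonstrates the procedures
  on planted truth instead, and reproduces the arm-level synergy
  arithmetic exactly.
* The growth model is single-compartment exponential; no survival, no
  mixed-effects longitudinal modeling, no dose–response fitting.
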