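# Methods and design notes

## Statistical model

### Beta values

The methylation level of a CpG is the fraction of methylated signal,
β = max(M, 0) / (max(M, 0) + max(U, 0) + 100), with M and U the
methylated/unmethylated channel intensities. Negative intensities (which
arise after background subtraction) are clamped to zero before the ratio.
The +100 offset keeps β strictly below 1 and shrinks low-intensity
(unreliable) probes toward 0; it bounds the inversion error of the
synthetic intensity model at roughly 100/T for total signal T.

### Differential methylation

Two-group comparisons use the two-sided Wilcoxon rank-sum test per unit.
When the pooled sample size is ≤ 12 and no ties are present, the exact
null distribution is enumerated (via scipy's exact method); otherwise the
normal approximation with continuity and midrank tie correction is used.
Constant pooled samples return p = 1. The continuity-corrected
approximation is mildly conservative at the cohort sizes used here
(differences up to ~0.015 from the enumeration at mid-range p, under
0.01 in the tail); this only makes the caller stricter.

P-values are Benjamini–Hochberg adjusted across all units of a contrast;
sites and regions are adjusted separately, each over its own unit set. A
site is a DMS at q < 0.05 and |Δβ| > 0.20; a region is a DMR at q < 0.05
and |Δβ| > 0.15. Δβ is the difference of group means (not medians), so
the effect-size gate is on the same scale as the reported thresholds.

Regions are unweighted means of member-probe betas per sample, grouped
either by (gene × gene-model category) or by the pooled promoter
definition (TSS200, TSS1500, 5'UTR, 1st exon). Testing happens on the
region means rather than on pooled member sites; pooling member sites
would inflate the effective sample size by treating correlated probes as
independent. Single-probe regions are tested but flagged as singletons.

### Biomarker machinery

A site set is scored per sample by its mean beta value (mBV), skipping
missing entries. Cutoff optimisation scans the midpoints of adjacent
unique scores plus one sentinel below the minimum and one above the
maximum; this grid attains the minimum misclassification count over all
real thresholds, because error counts only change when a threshold
crosses an observed score. Ties are broken toward the smallest
threshold, which favours sensitivity for hyper-methylation markers; the
rule is applied uniformly.

The ROC curve is built over all score thresholds with tied scores entering
as single diagonal steps, so the trapezoidal area equals the pairwise
concordance probability with ties counted one half (verified against
brute-force concordance and against scikit-learn in the tests).

Model comparison uses a paired, class-stratified bootstrap: each
replicate resamples sample ids with replacement within the disease and
normal classes separately, recomputes both models' AUCs on the same
resample and records the difference. The two-sided p-value is
2·min(tails) of the replicate differences around zero with +1 smoothing
in numerator and denominator (so p ∈ (0, 1] and is never exactly zero).
This is a paired-resampling formulation chosen because the two models
are evaluated on the same samples; an analytic (DeLong-style) variance
is deliberately out of scope.

### Classifier harness

The harness wires scikit-learn learners through a minimal fit/predict
contract: a random forest with 5000 trees (default), and a
single-hidden-layer network with 2 logistic hidden units, weight decay
10⁻⁴ and at most 400 iterations, fitted with L-BFGS. Logistic activation
is used because two rectified-linear units die too easily at this width,
making the small network's behaviour depend mostly on initialisation.
The default evaluation scheme is stratified 5-fold cross-validation with
pooled out-of-fold predictions collapsed into a single confusion matrix;
out-of-bag (random forest only) and resubstitution are selectable, since
published confusion matrices often leave the scheme unstated and the
ambiguity is better surfaced than hidden. Sensitivity and specificity are
computed by the same code path as the biomarker metrics.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is checked.

- **Manifest.** Each simulated gene receives one probe in each promoter
  category plus gene-body and 3'UTR probes, laid out in genomic order on
  an autosome; TSS200 probes always sit in a CpG island, other promoter
  probes mostly so. Sex-chromosome probes are intergenic, so sex
  filtering never destroys a promoter. Positions are 1-based and strictly
  increasing per chromosome; SNP flags are assigned at the requested rate.
- **Baselines.** Per-probe baseline levels come from a two-component beta
  mixture (modes 0.10 / 0.85, concentration 30). The island relation
  biases component assignment by odds weighting (islands 85% low-mode,
  open sea 20%), reflecting that CpG islands are mostly unmethylated in
  normal tissue; the global mixing weight still forces a single component
  at its extremes. Per-sample values are mean-preserving beta noise
  around the baseline (concentration 60, i.e. s.d. ≈ 0.06 at β = 0.5),
  plus a per-sample global offset (s.d. 0.04) added to all probes of a
  sample. The offset models the individual-level global methylation
  differences real cohorts show — without it, per-sample mean-beta
  comparisons between groups would be degenerate and any multi-site mean
  score would separate groups perfectly regardless of effect size.
- **Effects.** Stage-wise additive beta-scale shifts with clamping to
  [0, 1], monotone along LGA → HGA → cancer by default
  (hyper: +0.25/+0.30/+0.32; hypo: −0.25/−0.28/−0.30), at 150 hyper and
  300 hypo sites in the demo configuration (hypo outnumbering hyper
  roughly 2:1, as in adenoma tissue). Hyper effects are injected at
  probes with baseline mean < 0.5 and hypo at > 0.5 — disease
  hyper-methylation targets normally-unmethylated promoter CpGs and
  vice versa — which also keeps the realised |Δβ| aligned with the truth
  table under clamping. Marker genes' promoter CpG-island probes jointly
  receive the hyper effect. Every injected (probe, stage) pair is
  recorded in the truth table.
- **Intensities.** β is inverted into M = βT, U = (1−β)T with optional
  Gaussian channel noise. Detection p-values are a two-point mechanism:
  passing entries get p ~ U(0, 10⁻⁴), a configurable fraction of failing
  entries get p ~ U(0.01, 1]. No background-signal model is attempted
  since detection p is only ever used as a pass/fail filter.
- **Cohort sizes.** The demo defaults are 20 normal / 18 LGA / 22 HGA
  plus a 20-sample cancer arm, a typical size for an adenoma progression
  array study, with 4000 probes over 150 genes — large enough for stable
  FDR behaviour, small enough that the full pipeline runs in well under
  a minute.

**What the generator does not emulate:** probe-type (Infinium I vs II)
chemistry differences, batch or slide effects beyond the per-sample
offset, spatially correlated comethylation along chromosomes, cell-type
composition, and realistic detection-failure clustering. Passing tests
therefore demonstrate the correctness of the statistical machinery under
a clean, bimodal, effect-injected model — not robustness to the
technical artefacts of real arrays, which is what normalisation methods
(out of scope here) address.

## Preprocessing decisions

- Filter order is sex → detection → SNP; a probe is attributed to the
  first rule that removes it, so the report's counts always sum to the
  input count.
- Two detection-failure policies exist in practice: strict removal when
  any sample fails, and imputation of failed entries. Both are
  implemented (`fail_rule='any_sample'` vs `'fraction'` plus
  `impute_failed`); removal is the default.
- "Nearest-neighbour" imputation means the nearest non-failed flanking
  probes by genomic position on the same chromosome within the same
  sample, averaging the two flanks (one at chromosome ends). A
  per-position alternative across samples was rejected because it erases
  the per-sample signal that downstream group tests rely on.
- Unannotated probes are retained with a warning: each removal rule
  requires positive evidence (a sex chromosome, a SNP flag), which an
  absent annotation cannot provide.
- Array normalisation (control-probe scaling, background subtraction) is
  out of scope; the pipeline accepts normalised betas or raw M/U values.

## Numerical and reporting conventions

- Coordinates are 1-based inclusive in manifests, converted to 0-based
  half-open only in BED export.
- Direction percentages are reported to one decimal in percent;
  error rates to two decimals in percent; sensitivity, specificity and
  AUC to three decimals. Underlying unrounded values are available on
  the returned objects.
- All generators and resampling procedures are pure functions of their
  arguments and an integer seed; the pipeline derives a named seed per
  stage from the master seed and echoes the registry in the run report,
  which reproduces bit-identically under the same configuration.
- The demo pipeline overrides the random-forest default to 1000 trees
  (echoed in the report's override block) — at 80 samples the pooled
  cross-validated confusion matrix is already stable there.

## Known limitations

- The DMR unit is the gene-model region mean; sliding-window or
  bump-hunting detectors are not implemented.
- BH-FDR assumes positive-dependence-type regularity; the per-sample
  global offset induces mild cross-probe correlation, and the null
  calibration test confirms control empirically rather than by theorem.
- The bootstrap comparison p-value is resolution-limited at 2/(B+1); it
  reports strength of evidence for an AUC difference, not an effect size.
- With clean synthetic noise, multi-site mBV scores separate groups
  almost perfectly; discrimination-performance numbers on synthetic
  cohorts are upper bounds, not estimates of performance on real tissue.
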