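# Methods

## Problem and scope

`pam50kit` implements the cross-platform intrinsic-subtyping workflow for
breast tumors profiled simultaneously on a digital multiplexed counter
(NanoString-style probe counts) and on RNA-Seq: platform-specific
normalization to classifier-ready log2 matrices, the PAM50 nearest-centroid
call with an ambiguity rule and risk-of-recurrence (ROR) scores, and the
between-platform agreement statistics used to decide whether the two
technologies are interchangeable for subtyping. Because clinical cohorts of
this kind are rarely public, the package carries a synthetic paired-cohort
generator with full ground truth; every statistic is exercised against that
truth and against small brute-force oracles.

Out of scope: read alignment and transcript quantification (MapSplice/RSEM
and similar published tools), wet-lab QC, full RCC metadata (lanes, FOV,
binding density), survival modeling, and plot rendering.

## Normalization

**Digital counts.** Per sample, the background estimate is
`b = max(mean(neg) − m·sd(neg), 0)` over the negative-control probes
(sample SD, ddof = 1; `m` = 2 by default). `b` is subtracted from every
endogenous and housekeeping count and the result floored at a small
positive constant (default 1 count) so the later log2 is defined; negative
and positive control probes are dropped. Counts are then divided by the
per-sample geometric mean of the configured housekeeper genes and
log2-transformed. The housekeeper set is always supplied by configuration —
the panel's five housekeepers vary between codesets — and the generator's
default panel (ACTB, MRPL19, PSMC4, RPLP0, SF3A1) is only a default.
Subtraction (rather than thresholding) is used for the mean-minus-2SD rule
because the estimate is a background level to be removed; the floor handles
the counts it would push below zero. The whole recipe is invariant to
scaling a sample's counts by a constant, since the housekeepers scale too.

**RNA-Seq.** Genes detected (nonzero) in at least 70% of samples define the
quantile set; each sample is rescaled so the 75th percentile of that set
equals a fixed target (default 1000), then transformed as `log2(x + 1)`.
The pseudocount is the conventional choice for count data; the digital arm
needs none because the floor guarantees positivity. Finally each gene is
centered by an externally supplied reference median — in the clinical
workflow an estrogen-receptor-balanced FFPE reference that aligns test
samples with the classifier's training distribution. Reference medians are
an input, never recomputed from the cohort at hand: a triple-negative
cohort is maximally ER-unbalanced and self-centering would shift every
luminal gene.

The step order is fixed and enforced: background → housekeeper → classifier
for counts, and upper-quartile → log2 → median-center → classifier for
RNA-Seq.

## Classification

For each sample the Spearman correlation (Pearson optional) with each of
the five subtype centroids (Basal, Her2, LumA, LumB, Normal) is computed
over the centroid gene set; the call is the argmax. Spearman makes every
call invariant to strictly increasing per-sample transforms, which is why
the digital arm can be classified without gene centering. When the
runner-up centroid is within 0.10 of the winner the call is flagged
*ambiguous*: either subtype is plausible. Exact ties resolve
deterministically in the order Basal < Her2 < LumA < LumB < Normal and are
flagged ambiguous.

Confidence is `(top − second) / max(top, 1e-8)`, clipped to [0, 1]. This is
this package's own convention — a relative margin — chosen because
published classifier outputs report a confidence without a standardized
formula; it is monotone in the margin and 0 at a tie.

**Risk of recurrence.** `ROR = Σ w_k · ρ_k` over subtypes (ROR-S), plus
`w_p · P` for ROR+PS, where `P` is the mean log2 expression of the 11
proliferation genes (CCNB1, UBE2C, BIRC5, KNTC2, CDC20, PTTG1, RRM2, MKI67,
TYMS, CEP55, CDCA1). The raw score is mapped linearly onto 0–100 via
configured rescale bounds and clipped. Weights, bounds and the low/med/high
cutoffs are configuration data (`data/pam50_config.json`), not code: the
defaults use the classic subtype weights (0.05 Basal, 0.12 Her2, −0.34
LumA, 0.23 LumB for ROR-S), symmetric rescale bounds equal to the weight
envelope, and cutoffs (29, 53) for ROR-S and (23, 52) for ROR+PS under a
half-open convention (a score at a boundary takes the upper group). These
cutoffs reproduce the published worked example shipped in
`data/ror_reference_calls.json` (14 score→group pairs per ROR variant).
Whether the Normal-like centroid contributes to ROR is decided by the
coefficient file; an absent weight means 0.

## Agreement statistics

* **Raw concordance** — fraction of samples with identical calls.
  **Adjusted concordance** applies the ambiguity rule to discordant pairs:
  a pair is *rescued* when either platform's top-two gap is ≤ 0.10 and that
  platform's second call matches the other platform's call. A near-tie
  whose second call does not match is labelled `near_tie_unresolved`; by
  default (`count_any_near_tie=True`) it still counts toward adjusted
  concordance — the classification is declared undecidable rather than
  discordant — but both tallies always appear in the records, so either
  accounting can be read off the report.
* **Cohen's kappa** on the 5×5 call cross-table, computed from observed and
  marginal-expected agreement; when both raters are constant and equal
  (expected agreement 1) kappa is defined as 1 with a warning.
* **ICC**, two-way model, single measures, in both the consistency
  (ICC(3,1)) and absolute-agreement (ICC(A,1)) definitions, with F-based
  95% confidence limits (McGraw & Wong). Consistency is the headline
  variant; absolute agreement is reported beside it because a pure
  between-platform offset lowers only the latter. Zero between-subject
  variance yields ICC 0 with a warning.
* **Bland-Altman**: per-pair differences, their mean and SD (ddof = 1), and
  limits `mean ± 1.96·SD`.
* **Per-gene agreement**: cross-platform Spearman rho (+ raw p-value) and
  ICC per shared gene, binned as >0.9 / (0.8, 0.9] / (0.7, 0.8] / ≤0.7,
  with the median and mean ICC. p-values are not corrected for multiple
  testing across genes (the report notes this); a gene constant in either
  platform is recorded as missing with a reason rather than dropped
  silently.
* **Risk-group discordance**: counts of samples whose ROR (and separately
  ROR+PS) group differs between platforms, with per-sample records.
* **Cohort summaries**: mean, extrema and a t-based 95% CI for quality
  metrics such as RNA integrity numbers.

## Synthetic paired cohorts

The generator emulates a 96-sample triple-negative cohort profiled on both
platforms. Defaults: subtype mixture Basal 0.82, Her2 0.13, LumA 0.04,
LumB 0.01, Normal 0 (a TNBC call distribution, not a population
prevalence); 50 genes named after the signature panel (plus 5 housekeepers
and 8 negative probes); within-subtype biological SD 0.6 log2 units;
platform noise SD 0.2 log2 units per platform; digital count magnitude 600
with a per-sample depth factor (log2 SD 0.15); RNA-Seq library sizes drawn
uniformly from 2·10⁵–10⁶ with fractional (RSEM-style) expected counts;
negative probes Poisson with mean 8. The biological SD deliberately exceeds
the technical noise — in real cohorts biological variation dominates
platform error — which is what places the per-gene agreement of the default
conditions in the high-agreement regime typical of such comparisons.

Per sample, a subtype is drawn from the mixture and the biological log2
profile is that subtype's centroid plus gene-wise Gaussian noise; both
platforms observe that profile through their own noise and count model.
`injected_discordance=k` resamples the RNA-Seq profile of k samples from a
different subtype's centroid (the most probable alternative), creating
known cross-platform call flips; a degenerate mixture with no alternative
subtype raises an error.

Synthetic centroids are a labelled stand-in for the published centroid
matrix, not a reproduction: five Gaussian profiles with the documented
correlation structure (Basal anti-correlated with LumA; Her2 positively
correlated with LumB; Normal-like largely independent). The Her2→LumB
coupling is kept moderate (rank correlation ≈ 0.75): if two centroids
correlate above ~0.9, even noise-free samples of one subtype fall inside
the classifier's 0.10 ambiguity band and the subtypes are not identifiable
by construction.

Reference medians for the RNA-Seq arm are produced by pushing one
noise-free pseudo-sample per subtype through the upper-quartile + log2
recipe and taking per-gene medians — a balanced pseudo-reference on the
normalized scale, so centering does not depend on the cohort's own subtype
imbalance. Housekeeper truth sits at log2 level 0 with small noise
(SD 0.05), so geometric-mean scaling returns profiles on the biological
log2 scale and the two platforms' proliferation scores are directly
comparable.

What the generator does *not* model: FFPE degradation, GC and
fragment-length bias, probe-specific efficiencies, read-level sampling.
Passing tests therefore demonstrate the correctness of the *pipeline
arithmetic and its statistical behavior under a plausible noise model*, not
the assay's performance on real tissue.

## Numerical choices and degenerate inputs

* TSV floats are written with 17 significant digits and read with
  round-trip float parsing, so writer/reader pairs are bitwise lossless.
* Spearman on a constant vector, missing centroid or proliferation genes,
  fewer than 2 negative probes, a zero upper quartile, or a missing
  reference median all raise named errors; samples are never silently
  dropped or imputed (the centroid profile needs all 50 genes).
* Gene identifiers are case-sensitive symbols; cross-platform matching goes
  through an explicit alias map (legacy panel symbols KNTC2→NDC80,
  CDCA1→NUF2, ORC6L→ORC6 ship as a default). Two genes collapsing onto one
  canonical symbol is an error, never an average.
* Problem sizes in the test-suite and acceptance script: cohorts of 96
  samples (the emulated cohort size) for end-to-end checks, 200 for the
  noise-monotonicity property, 2000 for mixture-frequency calibration, and
  10⁴ pairs for the Bland-Altman coverage check; these sizes give the
  binomial/Gaussian tolerances used in the assertions.

## Known limitations

* The ROR+PS subtype weights and both sets of rescale bounds are this
  package's configuration defaults; studies using the original assay
  scripts should supply their own coefficient JSON.
* The confidence value is not comparable with confidences printed by other
  PAM50 implementations.
* ICC confidence limits assume the balanced two-rater Gaussian ANOVA model;
  bootstrap intervals are not implemented.
* The `rcc_like` reader accepts only the CodeSummary block of RCC exports.
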