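# Methods

This note documents the models implemented in `libio`, the parameter choices
that matter, the synthetic-data generator the tests run on, and the numerical
conventions used where the underlying method family admits more than one
reasonable definition.

## The biomarker

The pipeline targets a blood-based (liquid biopsy) predictor of immune
checkpoint blockade response. Its premise: productive ICB responses are
visible in peripheral blood as (i) a monotone accumulation of effector memory
CD8⁺ T cells (T_em) over the treatment course, (ii) early clonal expansion of
T cells, strongest at the early on-treatment time point, and (iii) elevated
expression of T_em and B cell transcriptional programs. The LiBIO score
summarizes (iii) as the mean of two single-sample gene-set enrichment scores
and is calibrated into a fixed decision threshold per data modality.

## ssGSEA variant

ssGSEA is a family of rank-based statistics; the exact variant is pinned as
follows and logged with every run:

- Per sample, genes are ranked by expression with the largest value receiving
  rank *n*; ties are broken by stable gene order of the input matrix, so
  scores are invariant to gene-order permutation of tied blocks only through
  the deterministic tie rule, and fully invariant to any per-sample strictly
  monotone transform of expression.
- Walking genes in decreasing expression, an in-set gene contributes
  `rank^α / Σ_{set} rank^α` and an out-of-set gene `1/(n − |set|)`; the
  enrichment score is the **sum of the running difference** over all *n*
  positions (an integral-type statistic, not the maximum deviation).
- The weight exponent is α = 0.25.
- With normalization on, per-set scores are divided by (max − min) of that
  set's scores across the samples of the call. Normalization is always
  **within cohort** — scores are never pooled across cohorts before
  normalization — so thresholds learned on one cohort apply to others on a
  comparable scale. A degenerate range (constant scores) returns raw scores
  with a warning rather than dividing by zero.

`LiBIO = (ES_Tem + ES_B)/2` holds exactly in every score table (asserted).

## Signature derivation

Markers are derived one-vs-rest at the early on-treatment time point (D9 in
the mouse design): per-gene two-sided Wilcoxon rank-sum on log-normalized
expression, BH adjustment over all genes surviving the detection filter,
retention at FDR ≤ 0.01 **and** fold change ≥ 1.5, up-regulated only. Fold
change is computed on the linear (de-logged) scale as
`(mean_in + ε)/(mean_out + ε)` with ε = 1; the scale and pseudocount are
recorded in the signature provenance. Mouse symbols pass through a strictly
one-to-one ortholog map (ambiguous or unmapped genes dropped and logged), and
a gene survives the cross-cohort filter only if it is detected (nonzero in at
least one sample) in **every** validation cohort — the strictest reading of
a detectability requirement, chosen because it is threshold-free.

## Repertoire statistics

Clonotype identity is `chain + ":" + CDR3 nucleotide sequence` (upper-cased);
paired-chain keys concatenate the per-chain keys sorted lexicographically.
Nucleotide-level within-chain identity is the strictest reproducible clone
definition. Clone size counts units (cells or reads) per key per sample; a
clone is expanded at size ≥ 2. Clonality is the Simpson dominance index
Σp² (higher = more expanded); an optional small-sample rescaling
`(Σp² − 1/S)/(1 − 1/S)` is available behind a flag since conventions differ.
Responder-vs-non-responder clonality uses the one-tailed Wilcoxon rank-sum
test (responders greater). Bulk-derived clonotypes are scoped per chain
(TRB for T, IGH for B lineages) by default, configurable.

## Statistical primitives

- **Wilcoxon rank-sum**: exact p by subset-sum enumeration of the
  Mann–Whitney U null when `n_x·n_y ≤ 200` and the pooled sample is
  tie-free; otherwise midranks, tie-corrected variance and a 0.5 continuity
  correction. The method variant and tie count are reported alongside p.
- **Fisher's exact test**: p by hypergeometric enumeration (two-sided sums
  tables no more probable than the observed, with the standard 1 + 10⁻⁷
  tolerance). The sample OR `(ad)/(bc)` gets a Haldane–Anscombe +0.5 on all
  cells when any cell is zero; the headline OR is the conditional MLE
  (solves E[a|ψ] = a on the noncentral hypergeometric by bisection), the
  convention of R's `fisher.test`, with the sample OR always reported too.
- **BH adjustment**: step-up with enforced monotonicity, capped at 1.
- **Mann–Kendall**: S = Σ_{i<j} sgn(x_j − x_i), tie-corrected variance with
  the Σ t(t−1)(2t+5) term, ±1 continuity correction, one-sided p. On four
  time points the smallest attainable one-sided p is ≈ 0.0447 (a strictly
  monotone sequence); the test is applied to time-ordered group means.

## Evaluation and calibration

AUC is the Mann–Whitney pair statistic (concordant pairs + half ties over
all responder × non-responder pairs), identical to the trapezoidal ROC
integral. Predicted-positive is `score ≥ threshold` (inclusive). The odds
ratio at a threshold is TP·TN/(FP·FN), Haldane-corrected and flagged when a
cell is zero. Calibration searches the midpoints of consecutive distinct
sorted scores — the complete set of achievable confusion tables — excluding
thresholds that empty a predicted class; ties on the (corrected) OR break to
higher balanced accuracy, then the lower threshold. The calibrated threshold
is applied *unchanged* to validation cohorts; per-cohort and mean ± SD
(sample SD, n−1) AUC/OR are reported, with single-class cohorts marked
OR-undefined. Calibrations are kept separate per modality (single-cell vs
bulk) because the generator, like real data, places single-cell scores on a
systematically higher scale.

## Survival

Kaplan–Meier is the standard product-limit estimator; the log-rank test uses
the pooled observed-minus-expected statistic with hypergeometric variance.
Dichotomization for KM/log-rank is at the mean score (ties at the mean go to
the low group, logged); the Cox model instead uses the continuous score, with
age and sex as covariates, complete-case on missing values. The partial
likelihood uses **Efron's** tie correction — better small-sample behavior
than Breslow — and is maximized by damped Newton iterations (step halving
until the likelihood does not decrease, 100-iteration cap); the fit reports
the gradient-converged flag, per-covariate HR = exp(β), Wald z and p.
Coefficients match `lifelines` to 1e-5 on shared test problems. Perfect
separation (monotone likelihood) is detected via coefficient blow-up and
flagged rather than silently reported.

## Fuzzy c-means and the elbow rule

Temporal profiles are per-gene means across a response group's samples at
each time point, z-scored across time points (constant genes become all-zero
and are flagged). Clustering uses the standard fuzzy c-means alternation with
fuzzifier m = 2, tolerance 10⁻⁶ on the max centroid shift, max 500
iterations, and centroid initialization from k distinct data points drawn by
the seeded generator; points coincident with a centroid get membership 1
(equal split over several). The recorded objective history is non-increasing
by construction and asserted in tests. The elbow rule is formalized as the
maximum second difference of the objective-vs-k curve; the k = 1 objective
(total sum of squares) anchors the curvature at the smallest candidate k, and
ties break to the smallest k.

## Synthetic-data generator

The generator emulates the *structure* of the study, not its biology:

- **Mouse time course** (defaults): 7 responders / 9 non-responders sampled
  at D4 (pre-treatment), D9, D17, D24; 400 cells per sample over six blood
  cell types; 300 genes with log-normal baselines and 15 markers per type
  elevated 8-fold; negative-binomial counts (NB2 dispersion 0.5); 10% of
  cells planted to fail QC (high mito or low gene detection, recorded as
  ground truth). Responder T_em proportions rise monotonically
  (+0, +0.05, +0.10, +0.15 over the four days); non-responders show a modest
  rise then decline (+0, +0.02, −0.02, −0.01).
- **Clonotypes**: per-subject clone pools with Dirichlet-multinomial
  frequencies; the Dirichlet concentration is the expansion knob (responders
  3 at D9 vs 40 elsewhere; non-responders 40 throughout — lower concentration
  = heavier clone-size tail). T_em cells draw clones size-biased
  (probability ∝ frequency², one knob), so expanded clones concentrate in
  the effector memory compartment.
- **Human validation cohorts**: log-normal TPM (bulk) or negative-binomial
  cells aggregated to pseudobulk (single-cell); responders get a +d
  standardized shift on signature genes (default d = 1.5); single-cell
  cohorts add +0.75 to signature-gene log₂ baselines so their scores run
  systematically higher than bulk; survival times are exponential with
  hazard ∝ exp(β·latent score) (default β = 0.7) under independent
  exponential censoring (default rate 0.3).
- Lightweight entry points (`simulate_clonotype_cohort`,
  `simulate_abundance`, `simulate_survival`) expose single components of the
  same models for repeated power/size simulations.

What the generator does **not** model: batch effects beyond the modality
offset, doublets, ambient RNA, sequence-level realism of CDR3s, gene–gene
correlation beyond cell-type structure, covariate-dependent censoring, or an
HPV/cancer-type covariate. Passing tests therefore demonstrate correctness of
the pipeline's computations and its behavior under the assumed statistical
structure — not performance on real patient cohorts, where effect sizes are
far smaller and structured noise dominates.

## Problem sizes and calibration checks

Power and calibration checks run at deliberately modest sizes chosen to keep
the full suite fast while leaving wide Monte-Carlo margins: 100–1000 seeds
for null-uniformity and power (clonotype/abundance components only), 50
seeds × n = 500 for Cox recovery, 200 random instances for each oracle
equivalence sweep. Null p-value uniformity for the clonality comparison is
checked with a Kolmogorov–Smirnov test at 20 + 20 samples per group, where
the exact Wilcoxon support is fine enough for the continuous uniform
reference; the trend test on four time points has a support of only a few
p-values, so its null behavior is checked as a size bound (rejection rate
≤ 0.05 + 2·MC-SE) rather than by a distributional test that no discrete test
statistic could pass.

## Known limitations

- The ssGSEA variant (integral ES, α = 0.25, range normalization) is one
  pinned member of a family; scores are not numerically comparable to other
  implementations, though rank-based conclusions are robust.
- The elbow rule requires evaluating one k below the candidate range; for
  k_min = 2 this uses the closed-form k = 1 objective.
- The conditional-MLE odds ratio is reported alongside the sample OR because
  published ORs rarely state their convention; the two can differ noticeably
  in small or unbalanced tables.
- Threshold calibration maximizes an odds ratio that is optimistically biased
  in-sample; the package reports training and validation ORs separately and
  never re-tunes on validation data.
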