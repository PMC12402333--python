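# libio

A liquid-biopsy transcriptomic biomarker pipeline for predicting response to
immune checkpoint blockade (ICB), built around the **LiBIO score**: the mean
of per-sample ssGSEA enrichment scores for an effector memory CD8⁺ T cell
(T_em) signature and a B cell signature derived from early on-treatment blood
single-cell data.

The package is aimed at computational immuno-oncology analysts who want a
tested, reproducible implementation of the full analysis chain — from raw
single-cell count matrices and clonotype tables to fixed decision thresholds
and survival association — together with a synthetic-cohort generator that
reproduces the statistical structure of the study design, so every stage can
be exercised and validated without access to patient data.

## What it computes

**LiBIO score.** For a sample with expression profile ranked so the most
expressed of *n* genes has rank *n*, the ssGSEA enrichment of a gene set *S*
is the sum over the ranked gene walk of the running difference

```
ES = Σ_positions [ Σ_{g∈S, reached} rank_g^α / Σ_{g∈S} rank_g^α  −  #{g∉S, reached}/(n−|S|) ]
```

with α = 0.25; per-set scores are range-normalized within a cohort, and
`LiBIO = (ES_Tem + ES_B) / 2` exactly.

Around this core the package provides:

- **Single-cell preprocessing** — QC (remove cells with >25% mitochondrial
  content or <500 detected genes), gene filtering (detected in <3 cells),
  counts-per-10⁴ log-normalization, ±marker gating (e.g. CD8 T: Cd8a⁺ Cd8b1⁺
  Cd4⁻), cell-type fractions, and de-logged-mean pseudobulk.
- **Signature derivation** — one-vs-rest Wilcoxon markers at the early
  on-treatment time point with Benjamini–Hochberg FDR ≤ 0.01 and linear fold
  change ≥ 1.5, mouse→human one-to-one ortholog mapping, and a
  detected-in-every-cohort expression filter.
- **Repertoire statistics** — clone sizes from CDR3-nucleotide clonotype
  keys, expansion calls (size ≥ 2), Fisher-exact enrichment of expansion in
  T_em vs other CD8 T cells, and Simpson dominance clonality Σp².
- **Temporal dynamics** — fuzzy c-means clustering of z-scored time-course
  profiles with elbow-based cluster-number selection, and Mann–Kendall
  monotone-trend tests of cell-type abundance.
- **Evaluation and calibration** — pair-counting ROC AUC, odds ratio
  OR = TP·TN/(FP·FN) at a fixed threshold, odds-ratio-maximizing threshold
  calibration, and cross-cohort transfer of the frozen threshold.
- **Survival** — Kaplan–Meier curves and log-rank tests on mean-dichotomized
  scores, and Cox proportional-hazards regression (Efron ties, Newton
  optimization) of survival on the continuous score adjusted for age and sex.
- **Statistics** — self-contained one-tailed Wilcoxon rank-sum (exact or
  tie-corrected normal), Fisher's exact test with sample and conditional-MLE
  odds ratios, BH adjustment, and Mann–Kendall, all cross-checked against
  independent oracles in the test suite.

## Worked example

Run the full synthetic study end to end (about ten seconds):

```bash
libio run --seed 1 --outdir demo
cat demo/summary.md
```

which prints:

```
## Validation performance

| metric | value |
|---|---|
| cohorts | 4 |
| AUC (mean ± SD) | 1.000 ± 0.000 |
| OR (mean ± SD) | 992.20 ± 817.15 |

## Fixed thresholds

- bulk: threshold 0.375 (training OR 1681.00)
- sc: threshold 0.658 (training OR 1681.00)
```

Reading the numbers: the generator plants a strong signature-gene elevation
(d = 1.5 per gene across ~30 genes) in responders of four validation cohorts,
so the LiBIO score separates responders perfectly (AUC 1.0) and the
odds ratios are the Haldane–Anscombe-corrected values of zero-error confusion
tables. The single-cell threshold (0.658) sits above the bulk threshold
(0.375) because single-cell cohorts receive a systematic positive offset on
signature-gene baselines, mirroring the modality difference the method has to
calibrate away. `demo/dynamics.json` records the planted monotone T_em rise
(Mann–Kendall p = 0.0447, the smallest attainable one-sided value at four
time points), and `demo/repertoire_tests.json` the Day-9 clonality difference
between responders and non-responders (one-tailed Wilcoxon p = 8.7 × 10⁻⁵)
and the enrichment of expanded clones in T_em cells (conditional-MLE OR 5.6).

The same stages are available individually (`libio simulate|qc|signature|
score|repertoire|dynamics|calibrate|evaluate|survival`), and as library
functions for use from Python.

## Layout

```
src/libio/        matrix.py (expression container + MTX/TSV IO)
                  tables.py (annotations, clonotypes, manifests)
                  stats.py · preprocess.py · signature.py · scoring.py
                  repertoire.py · dynamics.py · evaluate.py · survival.py
                  simulate.py (synthetic cohorts) · pipeline.py · report.py · cli.py
tests/            unit + property + acceptance suites (seeded, deterministic)
docs/methods.md   models, parameter choices, numerical conventions, limitations
```
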