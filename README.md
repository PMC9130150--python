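# immsig

Immune gene-expression signature scoring and outcome association for
HER2-positive breast-cancer trial cohorts.

Tumors with richer immune infiltration respond better to the anti-HER2
antibody trastuzumab, whose action is partly immune-mediated. `immsig`
implements the analysis pipeline used to study that relationship in
adjuvant and neoadjuvant anti-HER2 trial cohorts: platform-appropriate
normalization of expression counts, composite immune-subset scores, a
17-gene adaptive immune signature (AIS), a survival-supervised procedure
for deriving such signatures, and the downstream association analyses
(Kaplan–Meier, Cox proportional hazards, pathologic complete response
odds ratios). Because patient-level trial data are access-restricted, the
package ships a synthetic cohort generator with the same statistical
structure, so every stage is testable end to end.

## The methods in brief

**Normalization.** NanoString-style panel counts are scaled per sample so
that the geometric mean of designated housekeeping genes (default: *B2M,
GAPDH, POLR2A, UBC, YWHAZ*) equals the grand geometric mean, then
log2-transformed with pseudocount 0.5. RNA-seq counts go through a
conditional quantile normalization (cqn): log2 CPM corrected for smooth
GC-content and gene-length effects estimated by spline quantile
regressions at several quantile levels per sample.

**Scoring.** An immune-subset score is the arithmetic mean of the panel
genes' log2 expression — the log2 geometric mean of the linear-scale
values. CD45 (*PTPRC*) is scored as a single-gene panel. The AIS score of
sample *s* with signature genes *g₁…g₁₇* is

    raw_s = (1/17) Σᵢ x_{gᵢ,s},     AIS_s = (raw_s − mean(raw)) / sd(raw)

so scores have cohort mean 0 and variance 1 (n−1 denominator). Every
score is dichotomized at the cohort median (score ≤ median → "low").

**Derivation.** Genes are screened one at a time with univariate Cox
models on unit-SD expression (Efron ties); genes with p < 0.05 are tested
for over-representation in user-supplied gene sets (GMT) with the
upper-tail hypergeometric probability and Benjamini–Hochberg q-values;
the new signature is the overlap between the screen hits and the
top-enriched set.

**Association.** Kaplan–Meier curves with Greenwood variance and
log(−log) CIs, log-rank tests, per-arm-subset Cox fits (unadjusted and
adjusted for age, nodal status, ER/PR status, tumor size, grade), and
per-arm pCR odds ratios with Wald and profile-likelihood CIs.

## Worked example

Simulate a cohort in which one standard deviation of the latent immune
factor multiplies the hazard by 0.66 in anti-HER2 arms but not under
chemotherapy alone, then score and associate:

```sh
immsig simulate --seed 42 --n-samples 300 --out demo/cohort
immsig score --expression demo/cohort/expression.tsv \
             --panels demo/panels.yaml --out demo/out   # panels from truth.json
immsig associate --scores demo/out/scores.tsv --clinical demo/cohort/clinical.tsv \
                 --control-arms chemo --anti-her2-arms trastuzumab,combination \
                 --out demo/out
```

The unadjusted forest rows for the signature panel read:

```
   panel    subset    hr  ci_low  ci_high  p_value   n  n_events
adaptive       all 0.782   0.539    1.136    0.198 300       111
adaptive   control 1.396   0.751    2.593    0.292  97        43
adaptive anti_her2 0.537   0.327    0.879    0.013 203        68
```

Signature-high patients do markedly better in the anti-HER2 subset
(HR 0.54, p = 0.013) and no better under chemotherapy alone (HR 1.40,
p = 0.29) — the interaction pattern the generator planted.

The shipped printed-table fixtures reproduce the published pCR
contingency results without any synthetic data:

```sh
$ immsig reproduce-tables --out demo/tables
                         comparison  odds_ratio
             lapatinib: high vs low        1.67
           trastuzumab: high vs low        6.61
           combination: high vs low        0.81
AIS-low: combination vs trastuzumab        9.65
ER/PR x group chi-square p = 0.0235
```

Signature-high patients had 6.61-fold higher odds of pCR on trastuzumab
alone; signature-low patients had 9.65-fold higher odds when lapatinib
was added to trastuzumab. The reconstructed arm denominators (85, 77, 82)
independently match the three arms' reported sample sizes, and the
profile-likelihood CIs written to `demo/tables/` match the published
intervals to two decimals.

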