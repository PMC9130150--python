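# Methods

This note documents the models, parameter choices and numerical decisions
behind `immsig`, and what the synthetic-data tests do and do not establish
about real cohorts.

## Synthetic cohort model

The generator (`immsig.synthetic`) emulates the statistical structure the
downstream analysis relies on, not the marginal distributions of any real
trial.

**Expression.** Each sample carries a latent immune-infiltration factor
z ~ N(0, 1). Gene g in sample s has log2 mean

    log2 μ_gs = b_g + λ·z_s·1[g ∈ immune panel] + f_gc(GC_g) + f_len(len_g)

plus a per-sample library-size factor drawn uniformly from
`library_size_range` (default 0.7–1.3). Baselines b_g are N(5, 1.5²) for
background genes, N(6, 1²) for panel genes and N(9, 0.25²) for
housekeeping genes (stable and high, as housekeeping normalization
assumes). λ = `infiltration_loading` defaults to 1 log2-unit per SD of z —
a strong but realistic infiltration gradient that makes a 17-gene mean
track z with correlation ≈ 0.98, so score-recovery tests isolate pipeline
error rather than assay noise. Counts are negative binomial with
var = μ + φμ² and φ = 0.05. GC and length biases are smooth odd cubics
(0.75u + 0.25u³, u rescaled to [−1, 1]) whose amplitude parameters set the
maximum absolute log2 offset; both default to 0. Gene GC is uniform on
[0.3, 0.7] and lengths are log-uniform on [500, 10000] bp.

**Survival.** Event times are exponential with hazard
h₀·exp(β_arm·z): β_arm = `main_log_hr` (default log 0.96) in the
chemotherapy-only arm and `main_log_hr + interaction_log_hr` (default
log 0.66) in anti-HER2 arms — the treatment × signature interaction is
the structure of scientific interest. The exponential baseline is the
simplest proportional-hazards-consistent choice; Cox estimation is
invariant to the baseline, so any PH baseline would preserve hazard-ratio
recovery. Censoring is independent administrative truncation C ~ U(0, τ),
with τ calibrated by root-finding so the expected censored fraction equals
`censor_rate` (default 0.65, mirroring follow-up truncation); realized
fractions land within ±0.05 at n ≥ 1000.

**pCR.** Bernoulli with logit = a_arm + b_arm·z. Defaults make the
signature strongly predictive on trastuzumab alone (b = 1.1), nearly
inert on chemotherapy (0.1) and flat at a high rate on the combination
(−0.1 with intercept 0.05), the qualitative pattern the association stage
is meant to detect.

All draws come from one seeded `numpy.random.Generator` in a fixed order
(annotation, baselines, sample latents/arms/library sizes, counts,
survival, censoring, pCR, nuisance covariates), so a seed pins down the
cohort byte-for-byte. The truth record keeps z, the planted signature
genes and the housekeeping list for oracle tests. The first panel named in
`panel_spec` is recorded as the planted signature panel.

What the generator does **not** emulate: correlated gene-gene structure
beyond the single latent factor, assay-specific artifacts (lane effects,
probe cross-hybridization, mapping bias), covariate–outcome confounding
(nuisance covariates are independent of z), non-proportional hazards, and
informative censoring. Passing tests therefore demonstrate correctness of
the estimators under the assumed model, not robustness to those real-data
violations.

## Normalization

**Housekeeping route.** Per-sample scale factor = grand geometric mean of
housekeeping counts / that sample's housekeeping geometric mean; counts
are scaled, 0.5 added, log2 taken. Anchoring to the grand geometric mean
keeps output magnitudes comparable to the inputs. The housekeeping list
has set semantics (order and duplicates irrelevant). The pseudocount
(default 0.5, exposed) avoids −∞ at zero counts.

**Conditional quantile route.** y = log2((count + 0.5)/libsize × 10⁶);
within each sample, additive cubic B-spline quantile regressions of y on
(GC, log10 length) are fitted at `n_quantiles` (default 5) evenly spaced
levels; each gene's systematic offset — the mean-centered fitted surface,
linearly interpolated between levels at the gene's own within-sample
quantile — is subtracted; the sample is re-centered to its pre-correction
median so downstream standardization is unaffected by global shifts. The
contract is behavioral: ≥ 90 % removal of an injected 2-log2-unit
monotone GC trend, library-size-doubling invariance within 0.05, and
reduction to log2 CPM when no bias exists. Numerical equality with any
external cqn implementation is deliberately not a contract. Spline bases
use `spline_df` ≈ 5 functions per covariate; fits require several genes
per parameter and error out otherwise.

Both normalizers are permutation-equivariant in genes and samples. The
pipeline allows AIS scoring on either normalizer's output because panel
platforms normally use housekeeping scaling while GC/length correction is
an RNA-seq concern; the normalizer is an explicit config choice.

## Scoring and dichotomization

Subset scores are means of log2 values (log2 geometric means), so adding
c to every panel gene shifts the score by exactly c. The AIS score is the
gene-averaged normalized expression, standardized across the cohort with
the n−1 denominator (the variance-1 requirement does not fix the
denominator; n−1 is stated here as the package's convention). With two
samples the scores are ±1/√2 exactly. The configured panel size (17 for
the AIS) is validated against the supplied gene list.

Median dichotomization uses "score ≤ median → low": deterministic, and
the median sample itself is not called enriched. A degenerate all-tied
cohort yields an empty high group with a warning. Panel gene lists ship
as editable YAML config — the packaged subset panels and the 17-gene AIS
entry are illustrative placeholders, since validated lists are
user-supplied. CD45 is taken to be the single transcript PTPRC.

## Signature derivation

The screen fits one univariate Cox model per gene on unit-SD expression
(Efron ties), unadjusted by default (a config choice; adjustment is an
open design question in this procedure class), requiring ≥ 10 events;
zero-variance genes are skipped with a logged reason. Over-representation
uses the exact upper-tail hypergeometric probability against the screened
universe, with BH q-values reported but the top set chosen by raw p
(ties broken by set name for determinism). Replacing named GO/GSEA
tooling with the hypergeometric test keeps the statistic fully
implementable and testable; permutation-based enrichment and ontology
propagation are out of scope. The derived panel is the screen ∩ top-set
overlap, scored with the standardized-mean method. The default screening
subset is the anti-HER2 arms, matching the scientific target (treatment-
specific benefit); `screen_arms: all` is available.

## Survival and pCR analyses

Kaplan–Meier is computed natively (product-limit, Greenwood variance,
log(−log) CI by default) so the variance is exposed per time point;
hand-computed product-limit examples are the oracle. Log-rank delegates
to lifelines. Cox fits delegate to statsmodels PHReg, which supports both
Efron (default) and Breslow ties; a hand-coded partial-likelihood
grid-search oracle and an independent lifelines cross-check both agree
with it in the tests. Adjusted models use age, nodal status (ordinal
0–3), ER/PR (binary), tumor size and grade (ordinal), with collinearity
and constant-covariate guards; non-convergence (separation / monotone
likelihood) is flagged rather than reported as a fit. Hazard-ratio CIs
are Wald on the log scale.

Odds ratios are cross-products with Wald CIs
exp(log OR ± 1.96·√(Σ1/cell)) or profile-likelihood CIs from the
single-covariate logistic likelihood (intercept profiled out, likelihood
ratio inverted by root-finding). On the reconstructed printed tables the
profile intervals match the published CIs to two decimals, which Wald
intervals do not — the profile method therefore appears to be what the
published analysis used, and both are reported. Denominator
reconstruction from "rate % (count)" pairs takes the nearest integer n
and requires the rate to round-trip within 0.05 percentage points, else
it errors listing candidates; the reconstructed arm totals additionally
match the reported per-arm sample sizes (85/77/82). Chi-square is
uncorrected Pearson by default (Yates optional). Per-arm logistic fits of
pCR on group equal the cross-product OR algebraically and are
cross-checked as such.

## Problem sizes and tolerances

Test and acceptance simulations use cohorts of 300–1000 samples, 30–300
genes, 50 replicates for hazard-ratio recovery and 20–50 replicates for
power/ordering checks — sizes at which Monte-Carlo error is small enough
to separate correct from biased estimators while the whole suite stays
quick. Recovery assertions use 3-standard-error bands (binomial or
empirical); exact-arithmetic oracles use 1e-9–1e-12; the Cox-vs-grid
oracle uses 1e-3, limited by the grid refinement. Parameter-recovery Cox
fits use the generator's true latent score, because the per-SD effect is
defined on the latent scale; expression-derived scores would fold in an
attenuation factor that is a property of the noise level, not the
estimator (the latent-to-score correlation and full-pipeline recovery are
tested separately).

## Known limitations

* The cqn variant is a documented simplification; datasets with strong
  bias–expression interactions may be corrected less completely than by
  a full reference implementation.
* The profile CI uses a fixed ±30 log-OR search bracket; tables implying
  more extreme boundaries return ±∞ bounds.
* Exact published patient-level quantities (arm hazard ratios,
  Kaplan–Meier percentages, 6-year event-free survival) require the
  restricted trial data and are represented here only through
  parameter-recovery and pipeline-shape properties.
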