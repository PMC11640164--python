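# Methods

## Overview

`immunosig` quantifies the inferred infiltration of six T-cell
populations in bulk tumor transcriptomes and relates it to
checkpoint-inhibitor (ICI) outcome. The chain is:

1. expression on the log2(TPM+1) scale (log transform if TPM is supplied);
2. gene-symbol standardization via a small alias table;
3. location/scale empirical-Bayes batch adjustment;
4. sign-aware average z-score signature scoring;
5. rank tests across cancer types and between responders and
   non-responders, survival stratification, and AUROC validation.

All rank and survival statistics are implemented from first principles in
`immunosig.stats`; library implementations (scipy, statsmodels, sklearn,
lifelines, Bioconductor sva) appear only as independent cross-checks in
the test suite.

## Signature scoring

A signature is a marker panel with per-gene signs. For gene g and sample
s, z_{gs} = (x_{gs} − mean_g) / sd_g with mean and SD taken over a
reference population (SD uses the n−1 denominator; zero-variance genes
contribute z = 0 and are reported). The score of signature with markers
(g_i, w_i), w_i ∈ {+1, −1}, is

    score_s = (1/k) Σ_i w_i · z_{g_i s}.

Negative markers enter as sign-flipped z-scores (the early-dysfunctional
panel is PD-1+/CCR5+/TCF7+/Tim-3−, i.e. HAVCR2 carries w = −1); this is
the natural arithmetic for an "absence" marker and keeps the score a
plain average.

The default reference population is the pooled analysis cohort, so all
cancer types are scored on one z-axis and cross-type medians are directly
comparable; a per-type mode is available
(`AnalysisConfig(population="per_type")`) for within-type analyses.

A consequence of the n−1 denominator worth knowing: scores are invariant
to positive per-gene affine rescaling of expression, but *not* to
duplicating every sample — duplication rescales each z by
sqrt((2n−1)/(2(n−1))). The tests pin down this exact factor.

Built-in panels (canonical HGNC symbols): stem-like TILs
{TCF7, IL7R, CXCR5, CD28, CD27}; tissue-resident memory (TRM)
{CD69, ITGAE}; activated potentially-anti-tumor (APA)
{PDCD1, CD27, CD28, TNFRSF9, TNFRSF18}; early dysfunctional
{PDCD1, CCR5, TCF7, HAVCR2−}; late dysfunctional
{PDCD1, CD38, ENTPD1, CD101, HAVCR2}; BTN3A isoforms
{BTN3A1, BTN3A2, BTN3A3}. The union is 18 distinct genes. The alias
table maps the protein-level names PD-1/PD1 → PDCD1, Tim-3/TIM3 → HAVCR2,
CD103 → ITGAE, CD137 → TNFRSF9, GITR → TNFRSF18, CD39 → ENTPD1; all other
identifiers pass through verbatim (with a report).

## Batch adjustment

`combat_adjust` / `CombatAdjuster` implement the parametric
empirical-Bayes location/scale model with no covariates and no reference
batch: per-gene standardization by the grand mean and the pooled
batch-model residual variance; per-batch location (γ̂) and scale (δ̂²)
estimates on the standardized data; shrinkage of γ̂ toward a normal prior
and δ̂² toward an inverse-gamma prior with moment-matched hyperparameters,
solving the coupled posterior equations by fixed-point iteration
(relative tolerance 1e-6, cap 500 iterations); removal of the shrunken
effects and restoration of the original per-gene grand mean and pooled
variance. The grand-mean restoration is exact by construction (the
adjusted gene is re-centered), so adjusted matrices keep each gene's mean
to machine precision. Zero-pooled-variance genes pass through unadjusted
with a warning, never as NaN. A single batch is a pass-through.

The implementation agrees with Bioconductor `sva::ComBat` to ~1e-4 on
location+scale fixtures (the residual being sva's looser fixed-point
tolerance), which the test suite verifies through `Rscript`.

Two properties of genuine empirical-Bayes adjustment that users sometimes
find surprising, both verified in the tests: (i) when every gene carries
the *same* true batch shift, the between-gene variance of γ̂ is pure
sampling noise, the shrinkage weight is far from 1, and per-gene batch
means remain different after adjustment (only the shared component is
fully removed — here >95% of a 2.0 shift at 200 samples/batch); (ii)
adjustment is not strictly idempotent — a second pass moves values again,
but the passes contract geometrically.

## Outcome analyses

**Response rule.** Responders are ICI-treated patients with overall
survival ≥ 24 months from treatment initiation; non-responders died
before 24 months. Patients censored before the cutoff are unevaluable
and excluded (any forced label would be wrong with positive probability),
and untreated patients are never classified.

**Cross-cancer comparison.** Per signature and unordered pair of cancer
types: two-sided Mann–Whitney U on scores, group medians/IQRs, and a
Benjamini–Hochberg q within each signature's pairwise family. Flags are
reported under two conventions: q < 0.02 (FDR convention) and the p <
0.001 display threshold used for cross-type panels.

**Responder comparison.** Mann–Whitney per signature, BH across the six
signatures, flag at q < 0.02.

**Survival.** Treated samples are split at the median score per signature
(strictly-above-the-cut is "high", ties low; the quantile is
configurable), Kaplan–Meier curves per stratum, and the two-group
log-rank test with a χ²(1) reference (p = erfc(√(χ²/2))). Curves are
exported to a 120-month horizon.

**AUROC.** The rank AUROC of responder vs non-responder scores, equal to
U/(n₁n₂) with mid-rank U — the test suite asserts exact consistency with
the Mann–Whitney statistic. Multi-cohort runs report per-cohort AUROCs
plus an unweighted average per signature.

## Statistics kernel

* Mann–Whitney U from mid-rank sums; exact two-sided p by full
  enumeration of the C(n, n_a) group assignments (a permutation-exact
  test, valid with ties) when both groups have ≤ 8 observations or when
  requested explicitly; otherwise a tie-corrected normal approximation
  with continuity correction. Two-sided p is twice the smaller tail,
  capped at 1. The approximation's inherent worst-case deviation from
  the exact n=8/8 null is 0.0109 (at U = 24), which the tests assert.
* BH step-up: q_(i) = min_{j≥i} p_(j)·m/j, capped at 1.
* Kaplan–Meier over distinct event times; subjects censored exactly at an
  event time count as at risk for that event.
* Log-rank via hypergeometric moments per event time; ΣV = 0 returns
  χ² = 0, p = 1.

## Synthetic cohorts

The generator draws a genes × samples matrix containing the 18 signature
genes plus pure-noise decoy genes:

    x_gs = baseline + shift(type(s), g) + loc(batch(s)) + scale(batch(s))·ε,
    ε ~ N(0, gene_noise_sd²)

`shift` accumulates, over every signature containing g, the signed
per-(type, signature) effect w_g·δ(t, sig), so raising a signature's δ
always raises that signature's score, including through negative markers.
Batches act as location/scale effects on the noise, matching the
adjustment model's assumptions. Survival is exponential with rate
h = hazard_baseline·exp(−β·score), where the score is the chosen response
signature's score on the batch-free matrix — higher inferred infiltration
means longer survival. Censoring: with probability `censor_rate` a sample
receives an independent administrative censoring time C ~ U(0, 120)
months; event = (death ≤ C), so the realized censored fraction is below
`censor_rate`. Identical configurations (including the seed) generate
byte-identical output.

Defaults are the study conditions: 232 melanoma / 349 bladder / 664
ovarian / 647 pancreatic samples; ICI treatment restricted to a ~123
patient melanoma subset; two equal-probability batches with a +0.6
location and ×1.2 scale effect on the second; noise SD 1 (log2 units);
baseline hazard 0.02/month (median OS ≈ 35 months) with β = 0.5 on the
TRM score; censor rate 0.3; responder cutoff 24 months. The per-type
signature shifts are 1.1 / 0.6 / 0.45 / 0.0 z-units (melanoma / bladder /
pancreatic / ovarian) for all six signatures. The source studies report
only the qualitative ordering (with very small pairwise p-values at
hundreds of samples per type), so the magnitudes were fixed once by a
power analysis at the pipeline's prescribed recovery operating point —
the ordering of median scores must be recoverable for all six signatures
in ≥95% of seeds at 150 samples/type, which is demanding for the 2-gene
TRM panel and sets the ~0.45 z-unit floor on the smallest gap.

What the generator deliberately omits: count overdispersion, gene-gene
correlation beyond shared signature membership, isoform structure,
covariate-linked batch assignment, and non-exponential survival. Passing
tests therefore demonstrate correctness of the analysis machinery and
calibration under the assumed model, not robustness to real RNA-seq
artifacts.

## Numerical choices and degenerate inputs

* Zero-variance genes: z = 0 in scoring, pass-through in batch
  adjustment; both warn and report.
* All-tied rank tests: p = 1 (σ² = 0 branch).
* Median split of an all-tied score vector labels everything "low".
* Exact-test threshold: 8 per group (C(16,8) = 12,870 enumerations).
* Fixed-point tolerance 1e-6 / 500 iterations for the EB shrinkage.
* Problem sizes in the test suite and the acceptance script (200 null
  replicates of 120-sample cohorts, 25–40 recovery seeds at 150/type,
  500-per-arm AUROC checks) were chosen to give 3-binomial-SE resolution
  on the calibration bands while a full run stays in the tens of seconds.

## Known limitations

* The responder rule wastes follow-up information relative to a survival
  model; it is used because it is the validation design being reproduced.
* The log-rank χ²(1) reference is asymptotic; with very few events the
  null p is discrete and conservative.
* Batch adjustment assumes the batch/biology design is not confounded;
  the pipeline adjusts the full input matrix without covariates.
* Multi-cohort AUROC averaging is unweighted, so small cohorts count as
  much as large ones.
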