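# immunosig

Scoring and outcome analysis of T-cell infiltration signatures in bulk
tumor transcriptomes.

Solid tumors differ widely in how strongly T-cell populations infiltrate
their microenvironment, and that difference tracks the likelihood of
benefit from immune checkpoint inhibitors (ICIs): melanoma and bladder
cancer tend to respond, ovarian and pancreatic cancer rarely do. This
package estimates the infiltration of six T-cell populations — stem-like
tumor-infiltrating lymphocytes, tissue-resident memory (TRM) T-cells,
activated potentially-anti-tumor (APA) T-cells, early and late
dysfunctional T-cells, and the BTN3A isoform family — from the
co-expression of their marker genes, and relates the scores to cancer
type, ICI response, and overall survival. It is aimed at translational
researchers with a genes × samples TPM matrix and a clinical annotation
table.

## Method

Expression is carried as log2(TPM+1), optionally adjusted for batch with
the parametric empirical-Bayes location/scale model (ComBat). Each
marker gene g is standardized over a reference population,
z_g = (x_g − mean_g)/sd_g, and a signature with markers (g_i, w_i),
w_i ∈ {+1, −1}, scores each sample as the signed average

    score = (1/k) Σ_i w_i z_{g_i}

(so e.g. Tim-3⁻ in the early-dysfunctional panel enters with w = −1).
Scores are compared across cancer types and between ICI responders and
non-responders (responder: overall survival ≥ 24 months from treatment
start) with the Mann–Whitney U test and Benjamini–Hochberg FDR control;
survival is stratified by median score split with Kaplan–Meier curves and
the log-rank test; predictive value is summarized by the rank AUROC,
which equals U/(n₁n₂). The statistical kernel (exact and asymptotic
Mann–Whitney, BH, Kaplan–Meier, log-rank, AUROC) is self-contained and
cross-checked against scipy, statsmodels, lifelines, sklearn and
Bioconductor sva in the test suite. A synthetic cohort generator with
the same statistical structure (type-specific signature shifts, nuisance
batches, score-coupled exponential survival) makes the whole pipeline
testable without restricted patient data; see `docs/methods.md`.

## Worked example

```python
from immunosig import AnalysisConfig, combat_adjust, generate_cohort
from immunosig.pipeline import run_responder_comparison, run_survival
from immunosig.synthetic_data import default_config

cfg = default_config(seed=1)               # study-scale 4-type cohort
expr, annot = generate_cohort(cfg)
adjusted = combat_adjust(expr, dict(zip(annot.sample_id, annot.batch)))

analysis = AnalysisConfig()                # 24-month rule, median split
comparison = run_responder_comparison(adjusted, annot, analysis)
print(comparison[["signature", "p", "q", "significant_q"]].round(4))

survival, _ = run_survival(adjusted, annot, analysis)
print(survival[["signature", "logrank_chi2", "p",
                "median_os_high", "median_os_low"]].round(4))
```

prints

```
       signature       p       q  significant_q
0  stem_like_til  0.5536  0.6643          False
1            trm  0.0007  0.0042           True
2            apa  0.4749  0.6643          False
3      early_dys  0.3959  0.6643          False
4       late_dys  0.9076  0.9076          False
5          btn3a  0.1638  0.4913          False
       signature  logrank_chi2       p  median_os_high  median_os_low
0  stem_like_til        0.0027  0.9583         41.0269        34.7656
1            trm        7.8799  0.0050         51.1097        25.2574
2            apa        0.5084  0.4758         42.2031        29.4832
3      early_dys        0.4196  0.5171         32.4435        42.2031
4       late_dys        0.5882  0.4431         34.5922        42.2031
5          btn3a        1.4059  0.2357         28.0551        44.8596
```

In this cohort survival is coupled to the TRM score, and the analysis
recovers exactly that: TRM is the only signature whose
responder/non-responder difference survives FDR control (q = 0.004 <
0.02), and its high-score stratum lives roughly twice as long (median
51 vs 25 months, log-rank p = 0.005); the other five signatures behave
as nulls.

The same stages are available from the shell:

```sh
immunosig simulate --seed 17 --out cohort/
immunosig preprocess --expr cohort/expression.tsv --scale log2tpm1 \
    --annot cohort/annotation.csv --combat --out adjusted.tsv
immunosig score --expr adjusted.tsv --out scores.csv
immunosig run --expr adjusted.tsv --annot cohort/annotation.csv --out results/
```

`results/` then holds `cross_cancer.csv`, `responder.csv`,
`survival.csv`, `km_curves.csv`, `auroc.csv` and a run log.

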