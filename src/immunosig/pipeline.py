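"""End-to-end analyses: cross-cancer infiltration, responder comparison,
survival stratification, and AUROC validation.

All four analyses start from the same samples x signatures score table
(sign-aware average z-scores on a pooled reference axis, so different
cancer types live on one scale) and the per-sample clinical annotation.
Response to checkpoint inhibition is derived from overall survival with a
24-month rule: treated patients surviving >= 24 months are responders,
treated patients who died before 24 months are non-responders, and
patients censored before the cutoff are unevaluable and excluded.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .preprocess import ExpressionMatrix
from .signatures import GeneSignature, builtin_signatures, score_all

__all__ = [
    "AnalysisConfig",
    "classify_response",
    "compute_scores",
    "run_cross_cancer",
    "run_responder_comparison",
    "run_survival",
    "run_auroc_validation",
    "run_all",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
UNEVALUABLE = "unevaluable"

KM_HORIZON_MONTHS = 120.0


@dataclass
class AnalysisConfig:
    """Knobs of the analysis pipeline; defaults mirror the study design."""

    signatures: list[GeneSignature] | None = None
    population: str = "pooled"  # z-score reference: "pooled" or "per_type"
    responder_cutoff_months: float = 24.0
    survival_quantile: float = 0.5
    alpha: float = 0.05            # raw two-sided threshold
    fdr_q: float = 0.02            # FDR-adjusted threshold
    display_threshold: float = 0.001  # cross-cancer display convention
    seed: int = 0

    def __post_init__(self) -> None:
        if self.responder_cutoff_months <= 0:
            raise ValueError("responder cutoff must be > 0")
        if not 0.0 < self.survival_quantile < 1.0:
            raise ValueError("survival quantile must lie in (0, 1)")

    def resolved_signatures(self) -> list[GeneSignature]:
        return list(self.signatures) if self.signatures else builtin_signatures()


def classify_response(
    annot: pd.DataFrame, cutoff_months: float = 24.0
) -> pd.Series:
    """Responder / non-responder / unevaluable labels per sample.

    Only treated samples are classified. Responder: OS >= cutoff (alive or
    dead).  Non-responder: died before the cutoff.  Censored before the
    cutoff: unevaluable (their eventual survival is unknowable).
    """
    if cutoff_months <= 0:
        raise ValueError("cutoff must be > 0")
    labels = pd.Series(UNEVALUABLE, index=annot.index, name="response")
    treated = annot["ici_treated"].astype(bool)
    os_m = annot["os_months"].astype(float)
    event = annot["event"].astype(int)
    labels[treated & (os_m >= cutoff_months)] = RESPONDER
    labels[treated & (os_m < cutoff_months) & (event == 1)] = NON_RESPONDER
    return labels


def compute_scores(
    m: ExpressionMatrix, annot: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Samples x signatures score table under the configured reference.

    The matrix is restricted to the annotated samples first, so the
    z-score reference population is the analysis cohort.
    """
    ids = list(annot["sample_id"])
    missing = [s for s in ids if s not in set(m.sample_ids)]
    if missing:
        raise ValueError(f"annotated samples missing from matrix: {missing[:5]}")
    m = ExpressionMatrix(values=m.values[ids], scale=m.scale)
    sigs = config.resolved_signatures()
    if config.population == "pooled":
        return score_all(m, sigs=sigs)
    if config.population == "per_type":
        pieces = []
        annot = annot.set_index("sample_id")
        for _, members in annot.groupby("cancer_type").groups.items():
            sub = ExpressionMatrix(
                values=m.values[list(members)], scale=m.scale
            )
            pieces.append(score_all(sub, sigs=sigs))
        scores = pd.concat(pieces)
        return scores.loc[m.sample_ids]
    raise ValueError(f"unknown population mode {config.population!r}")


def _annot_indexed(annot: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    a = annot.set_index("sample_id")
    missing = scores.index.difference(a.index)
    if len(missing):
        raise ValueError(f"samples missing from annotation: {list(missing)[:5]}")
    return a.loc[scores.index]


def run_cross_cancer(
    m: ExpressionMatrix, annot: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Pairwise differential-infiltration tests across cancer types.

    For every signature and unordered pair of cancer types: Mann-Whitney U
    on the signature scores, group medians and IQRs, raw p and a
    Benjamini-Hochberg q computed within each signature's pairwise family.
    """
    scores = compute_scores(m, annot, config)
    a = _annot_indexed(annot, scores)
    types = sorted(a["cancer_type"].unique())
    if len(types) < 2:
        raise ValueError("cross-cancer comparison needs >= 2 cancer types")
    for t in types:
        if (a["cancer_type"] == t).sum() < 2:
            raise ValueError(f"cancer type {t!r} has fewer than 2 samples")
    rows = []
    for sig in scores.columns:
        for t1, t2 in itertools.combinations(types, 2):
            s1 = scores.loc[a["cancer_type"] == t1, sig].to_numpy()
            s2 = scores.loc[a["cancer_type"] == t2, sig].to_numpy()
            res = stats.mann_whitney_u(s1, s2)
            med1, med2 = float(np.median(s1)), float(np.median(s2))
            rows.append(
                {
                    "signature": sig,
                    "type_a": t1,
                    "type_b": t2,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "median_a": med1,
                    "median_b": med2,
                    "iqr_a": float(np.subtract(*np.percentile(s1, [75, 25]))),
                    "iqr_b": float(np.subtract(*np.percentile(s2, [75, 25]))),
                    "direction": t1 if med1 > med2 else t2,
                    "u_statistic": res.u_statistic,
                    "p": res.p_two_sided,
                }
            )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for sig in scores.columns:
        mask = table["signature"] == sig
        table.loc[mask, "q"] = stats.bh_adjust(table.loc[mask, "p"].to_numpy())
    table["significant_q"] = table["q"] < config.fdr_q
    table["significant_display"] = table["p"] < config.display_threshold
    return table


def _response_groups(
    scores: pd.DataFrame, a: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    response = classify_response(a, config.responder_cutoff_months)
    resp = scores.loc[response == RESPONDER]
    non = scores.loc[response == NON_RESPONDER]
    if len(resp) < 2 or len(non) < 2:
        raise ValueError(
            f"need >= 2 responders and non-responders "
            f"(got {len(resp)} / {len(non)})"
        )
    return resp, non


def run_responder_comparison(
    m: ExpressionMatrix, annot: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Responder vs non-responder score comparison per signature.

    Mann-Whitney U per signature with BH adjustment across the signature
    family; the significance flag uses the FDR convention (q < 0.02 by
    default).
    """
    scores = compute_scores(m, annot, config)
    a = _annot_indexed(annot, scores)
    resp, non = _response_groups(scores, a, config)
    rows = []
    for sig in scores.columns:
        res = stats.mann_whitney_u(resp[sig].to_numpy(), non[sig].to_numpy())
        rows.append(
            {
                "signature": sig,
                "n_responders": res.n_a,
                "n_non_responders": res.n_b,
                "median_responders": float(resp[sig].median()),
                "median_non_responders": float(non[sig].median()),
                "u_statistic": res.u_statistic,
                "p": res.p_two_sided,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = stats.bh_adjust(table["p"].to_numpy())
    table["significant_q"] = table["q"] < config.fdr_q
    return table


def run_survival(
    m: ExpressionMatrix, annot: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """High/low score stratification with Kaplan-Meier and log-rank.

    Treated samples are split at the configured quantile of each
    signature's score (ties to low); returns a per-signature summary
    (log-rank chi2 and p, per-stratum counts and median survival) and a
    long-format table of the product-limit curves up to 120 months.
    """
    scores = compute_scores(m, annot, config)
    a = _annot_indexed(annot, scores)
    treated = a["ici_treated"].astype(bool)
    if treated.sum() < 4:
        raise ValueError("survival analysis needs >= 4 treated samples")
    sub = a.loc[treated]
    sub_scores = scores.loc[treated]
    rows, curve_rows = [], []
    for sig in scores.columns:
        labels = stats.median_split(
            sub_scores[sig].to_numpy(), config.survival_quantile
        )
        strata = {}
        for name in ("high", "low"):
            mask = labels == name
            if mask.sum() == 0:
                raise ValueError(f"stratum {name!r} is empty for {sig!r}")
            strata[name] = (
                sub.loc[mask, "os_months"].to_numpy(),
                sub.loc[mask, "event"].to_numpy(),
            )
        lr = stats.logrank_test(*strata["high"], *strata["low"])
        row = {"signature": sig, "logrank_chi2": lr.chi2, "p": lr.p}
        for name in ("high", "low"):
            times, events = strata[name]
            km = stats.km_fit(times, events)
            median = _km_median(km)
            row[f"n_{name}"] = times.size
            row[f"events_{name}"] = int(events.sum())
            row[f"median_os_{name}"] = median
            frame = km.to_frame()
            frame = frame[frame["time"] <= KM_HORIZON_MONTHS]
            frame.insert(0, "stratum", name)
            frame.insert(0, "signature", sig)
            curve_rows.append(frame)
        row["significant"] = lr.p < config.alpha
        rows.append(row)
    summary = pd.DataFrame(rows)
    curves = pd.concat(curve_rows, ignore_index=True)
    return summary, curves


def _km_median(km: stats.KaplanMeierCurve) -> float:
    """Smallest event time with S(t) <= 0.5, NaN if never reached."""
    below = np.flatnonzero(km.survival <= 0.5)
    return float(km.times[below[0]]) if below.size else float("nan")


def run_auroc_validation(
    m: ExpressionMatrix,
    annot: pd.DataFrame,
    config: AnalysisConfig,
    cohort_col: str | None = None,
) -> pd.DataFrame:
    """Per-signature AUROC of responder vs non-responder scores.

    With ``cohort_col`` naming an annotation column, the AUROC is computed
    within each cohort and an unweighted "average" row per signature is
    appended.
    """
    scores = compute_scores(m, annot, config)
    a = _annot_indexed(annot, scores)
    cohorts = (
        [(None, a.index)]
        if cohort_col is None
        else [(c, idx) for c, idx in a.groupby(cohort_col).groups.items()]
    )
    rows = []
    for cohort, members in cohorts:
        resp, non = _response_groups(
            scores.loc[members], a.loc[members], config
        )
        for sig in scores.columns:
            rows.append(
                {
                    "cohort": cohort if cohort is not None else "all",
                    "signature": sig,
                    "n_responders": len(resp),
                    "n_non_responders": len(non),
                    "auroc": stats.auroc(
                        resp[sig].to_numpy(), non[sig].to_numpy()
                    ),
                }
            )
    table = pd.DataFrame(rows)
    if cohort_col is not None:
        avg = (
            table.groupby("signature", sort=False)["auroc"]
            .mean()
            .reset_index()
            .assign(cohort="average")
        )
        table = pd.concat([table, avg], ignore_index=True)
    return table


def run_all(
    m: ExpressionMatrix,
    annot: pd.DataFrame,
    config: AnalysisConfig,
    outdir,
) -> dict[str, pd.DataFrame]:
    """Run all four analyses and write their tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {"cross_cancer": run_cross_cancer(m, annot, config)}
    results["responder"] = run_responder_comparison(m, annot, config)
    survival, curves = run_survival(m, annot, config)
    results["survival"] = survival
    results["km_curves"] = curves
    results["auroc"] = run_auroc_validation(m, annot, config)
    for name, table in results.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    log = {
        "n_samples": int(m.shape[1]),
        "n_genes": int(m.shape[0]),
        "signatures": [s.name for s in config.resolved_signatures()],
        "responder_cutoff_months": config.responder_cutoff_months,
        "survival_quantile": config.survival_quantile,
        "thresholds": {
            "alpha": config.alpha,
            "fdr_q": config.fdr_q,
            "display": config.display_threshold,
        },
        "population": config.population,
        "seed": config.seed,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return results
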