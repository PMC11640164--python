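"""Synthetic multi-cancer cohorts with signature structure and survival.

The generator emulates the data structure the analysis pipeline assumes: a
bulk expression matrix (log2(TPM+1) scale) over four cancer-type strata,
where each cancer type shifts the member genes of each T-cell signature by
a configurable amount (z-units relative to the gene noise SD), nuisance
batches add location/scale effects, and overall survival is exponential
with a log-hazard that decreases in one chosen signature's score, so that
higher inferred infiltration means longer survival.  Decoy background
genes are pure noise.

Defaults mirror the study conditions: per-type sample counts of 232
melanoma / 349 bladder / 664 ovarian / 647 pancreatic, checkpoint-inhibitor
treatment restricted to a 123-patient melanoma subset, and per-signature
type shifts ordered melanoma > bladder > pancreatic > ovarian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import SCALE_LOG, SCALE_TPM, ExpressionMatrix, write_expression
from .signatures import GeneSignature, builtin_signatures, signature_gene_union

__all__ = [
    "SyntheticConfig",
    "default_config",
    "null_config",
    "generate_cohort",
    "export_tpm",
    "write_cohort",
    "ANNOTATION_COLUMNS",
]

ANNOTATION_COLUMNS = [
    "sample_id",
    "cancer_type",
    "batch",
    "ici_treated",
    "os_months",
    "event",
]

CANCER_TYPES = ("melanoma", "bladder", "ovarian", "pancreatic")

#: per-signature mean shift (z-units) per cancer type, emulating the
#: qualitative infiltration ordering melanoma > bladder > pancreatic > ovarian
DEFAULT_TYPE_SHIFTS = {
    "melanoma": 1.1,
    "bladder": 0.6,
    "pancreatic": 0.45,
    "ovarian": 0.0,
}

CENSOR_HORIZON_MONTHS = 120.0


def _default_effect_matrix() -> dict[str, dict[str, float]]:
    sig_names = [s.name for s in builtin_signatures()]
    return {
        t: {s: DEFAULT_TYPE_SHIFTS[t] for s in sig_names} for t in CANCER_TYPES
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_matrix`` maps cancer type -> signature name -> mean shift
    (log2 units, i.e. z-units when ``gene_noise_sd`` is 1) added to that
    signature's member genes, in the direction of the marker sign.  A gene
    shared by several signatures accumulates their signed shifts.
    """

    seed: int = 0
    n_per_type: dict[str, int] = field(
        default_factory=lambda: {
            "melanoma": 232,
            "bladder": 349,
            "ovarian": 664,
            "pancreatic": 647,
        }
    )
    n_background_genes: int = 50
    batch_assignment: dict[str, dict[str, float]] | None = None
    batch_location: dict[str, float] = field(
        default_factory=lambda: {"batch1": 0.0, "batch2": 0.6}
    )
    batch_scale: dict[str, float] = field(
        default_factory=lambda: {"batch1": 1.0, "batch2": 1.2}
    )
    effect_matrix: dict[str, dict[str, float]] = field(
        default_factory=_default_effect_matrix
    )
    gene_noise_sd: float = 1.0
    baseline_mean: float = 5.0
    hazard_baseline: float = 0.02
    hazard_coefficient: float = 0.5
    censor_rate: float = 0.3
    response_signature: str = "trm"
    ici_fraction: dict[str, float] = field(
        default_factory=lambda: {"melanoma": 123 / 232}
    )
    signatures: list[GeneSignature] | None = None

    def resolved_signatures(self) -> list[GeneSignature]:
        return list(self.signatures) if self.signatures else builtin_signatures()

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_type.values()):
            raise ValueError("sample counts must be >= 0")
        if sum(self.n_per_type.values()) == 0:
            raise ValueError("zero total samples")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.gene_noise_sd <= 0:
            raise ValueError("gene_noise_sd must be > 0")
        if self.hazard_baseline <= 0:
            raise ValueError("hazard_baseline must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if any(s <= 0 for s in self.batch_scale.values()):
            raise ValueError("batch scales must be > 0")
        sig_names = {s.name for s in self.resolved_signatures()}
        if self.response_signature not in sig_names:
            raise ValueError(
                f"unknown response signature {self.response_signature!r}"
            )
        for t, row in self.effect_matrix.items():
            if t not in self.n_per_type:
                raise ValueError(f"effect_matrix has undeclared cancer type {t!r}")
            for s in row:
                if s not in sig_names:
                    raise ValueError(f"unknown signature name in effect_matrix: {s!r}")
        if self.batch_assignment is not None:
            for t, dist in self.batch_assignment.items():
                if abs(sum(dist.values()) - 1.0) > 1e-9:
                    raise ValueError(f"batch probabilities for {t!r} must sum to 1")
                for b in dist:
                    if b not in self.batch_location or b not in self.batch_scale:
                        raise ValueError(f"batch {b!r} has no location/scale entry")


def default_config(**overrides) -> SyntheticConfig:
    """The study-conditions default, with optional field overrides.

    When ``n_per_type`` is overridden without an explicit ``effect_matrix``,
    the default effect matrix is restricted to the declared cancer types
    (unlisted types fall back to a zero shift).
    """
    cfg = replace(SyntheticConfig(), **overrides)
    if "n_per_type" in overrides and "effect_matrix" not in overrides:
        cfg.effect_matrix = {
            t: dict(cfg.effect_matrix.get(t, {})) for t in cfg.n_per_type
        }
    return cfg


def null_config(
    n_per_type: Mapping[str, int] | None = None, seed: int = 0, **overrides
) -> SyntheticConfig:
    """A zero-effect cohort: no type shifts, no batch effects, hazard flat.

    Every sample is treated, so responder and survival analyses run on the
    whole cohort; response status is then pure noise by construction.
    """
    if n_per_type is None:
        n_per_type = {"melanoma": 60, "bladder": 60}
    n_per_type = dict(n_per_type)
    cfg = SyntheticConfig(
        seed=seed,
        n_per_type=n_per_type,
        effect_matrix={t: {} for t in n_per_type},
        batch_location={"batch1": 0.0, "batch2": 0.0},
        batch_scale={"batch1": 1.0, "batch2": 1.0},
        hazard_coefficient=0.0,
        ici_fraction={t: 1.0 for t in n_per_type},
    )
    return replace(cfg, **overrides)


def _batch_probs(cfg: SyntheticConfig, cancer_type: str) -> tuple[list[str], np.ndarray]:
    if cfg.batch_assignment is not None and cancer_type in cfg.batch_assignment:
        dist = cfg.batch_assignment[cancer_type]
        names = sorted(dist)
        return names, np.array([dist[b] for b in names])
    names = sorted(cfg.batch_location)
    return names, np.full(len(names), 1.0 / len(names))


def _gene_shifts(
    cfg: SyntheticConfig, genes: list[str]
) -> dict[str, np.ndarray]:
    """Per-type additive shift per gene (signed accumulation over panels)."""
    sigs = cfg.resolved_signatures()
    gene_idx = {g: i for i, g in enumerate(genes)}
    shifts = {}
    for t in cfg.n_per_type:
        row = np.zeros(len(genes))
        for sig in sigs:
            delta = cfg.effect_matrix.get(t, {}).get(sig.name, 0.0)
            if delta == 0.0:
                continue
            for g, sign in sig.markers:
                row[gene_idx[g]] += sign * delta
        shifts[t] = row
    return shifts


def generate_cohort(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw one cohort: (log2-scale expression, per-sample annotation).

    Identical configs (including the seed) give identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sigs = cfg.resolved_signatures()

    sig_genes = signature_gene_union(sigs)
    bg_genes = [f"BG{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    genes = sig_genes + bg_genes

    types = sorted(cfg.n_per_type)
    sample_type = np.concatenate(
        [np.full(cfg.n_per_type[t], t, dtype=object) for t in types]
    )
    n = sample_type.size
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]

    batch = np.empty(n, dtype=object)
    ici = np.zeros(n, dtype=bool)
    for t in types:
        members = np.flatnonzero(sample_type == t)
        names, probs = _batch_probs(cfg, t)
        batch[members] = rng.choice(names, size=members.size, p=probs)
        frac = cfg.ici_fraction.get(t, 0.0)
        ici[members] = rng.random(members.size) < frac

    shifts = _gene_shifts(cfg, sig_genes)
    signal = np.full((len(genes), n), cfg.baseline_mean)
    for t in types:
        members = np.flatnonzero(sample_type == t)
        signal[: len(sig_genes), members] += shifts[t][:, None]

    noise = rng.normal(0.0, cfg.gene_noise_sd, size=signal.shape)
    clean = signal + noise

    loc = np.array([cfg.batch_location[b] for b in batch])
    scale = np.array([cfg.batch_scale[b] for b in batch])
    observed = signal + loc[None, :] + scale[None, :] * noise

    # survival is driven by the batch-free signature score
    clean_em = ExpressionMatrix(
        values=pd.DataFrame(clean, index=genes, columns=sample_ids),
        scale=SCALE_LOG,
    )
    from .signatures import score_all  # local import avoids cycle at import time

    scores = score_all(clean_em, sigs=sigs)
    driver = scores[cfg.response_signature].to_numpy()
    rate = cfg.hazard_baseline * np.exp(-cfg.hazard_coefficient * driver)
    death = rng.exponential(1.0 / rate)
    censored_flag = rng.random(n) < cfg.censor_rate
    censor_time = rng.uniform(0.0, CENSOR_HORIZON_MONTHS, size=n)
    censor_time[~censored_flag] = np.inf
    os_months = np.minimum(death, censor_time)
    event = (death <= censor_time).astype(int)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(observed, index=genes, columns=sample_ids),
        scale=SCALE_LOG,
    )
    annot = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cancer_type": sample_type,
            "batch": batch,
            "ici_treated": ici,
            "os_months": np.round(os_months, 6),
            "event": event,
        }
    )
    return matrix, annot


def export_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Invert the log transform: 2^x - 1, back to the TPM scale."""
    if m.scale != SCALE_LOG:
        raise ValueError("export_tpm expects log2(TPM+1) input")
    vals = np.power(2.0, m.values.to_numpy()) - 1.0
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=m.values.index, columns=m.values.columns),
        scale=SCALE_TPM,
    )


def write_cohort(outdir, m: ExpressionMatrix, annot: pd.DataFrame) -> None:
    """Write expression as TSV and annotation as CSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(m, outdir / "expression.tsv")
    annot.to_csv(outdir / "annotation.csv", index=False, columns=ANNOTATION_COLUMNS)
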