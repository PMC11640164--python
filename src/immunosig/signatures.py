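"""T-cell gene signatures and sign-aware average z-score scoring.

A signature is a named set of marker genes, each carrying a sign: +1 for
markers whose expression defines the population, -1 for markers whose
*absence* defines it (the early-dysfunctional panel is Tim-3 negative).
Scoring standardizes each gene across a reference population of samples
(z-score, n-1 denominator) and averages the signed z-scores of the
signature's markers, giving one number per sample per signature on a
common z-unit axis.

Six built-in panels cover stem-like tumor-infiltrating lymphocytes,
tissue-resident memory T-cells, activated potentially-anti-tumor (APA)
T-cells, early and late dysfunctional T-cells, and the butyrophilin 3A
isoform family.  Marker symbols are canonical HGNC: PD-1 is PDCD1, Tim-3
is HAVCR2, CD103 is ITGAE, CD137 is TNFRSF9, GITR is TNFRSF18, CD39 is
ENTPD1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import SCALE_LOG, ExpressionMatrix

__all__ = [
    "GeneSignature",
    "builtin_signatures",
    "signature_gene_union",
    "load_signatures_yaml",
    "save_signatures_yaml",
    "gene_zscores",
    "score_signature",
    "score_all",
    "SignatureScorer",
]


@dataclass(frozen=True)
class GeneSignature:
    """Named marker panel with per-gene sign (+1 / -1)."""

    name: str
    markers: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ValueError(f"signature {self.name!r} has no markers")
        genes = [g for g, _ in self.markers]
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate marker gene in signature {self.name!r}")
        for g, s in self.markers:
            if s not in (+1, -1):
                raise ValueError(f"sign of {g} in {self.name!r} must be +1 or -1")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.markers]

    @property
    def signs(self) -> np.ndarray:
        return np.array([s for _, s in self.markers], dtype=float)


def builtin_signatures() -> list[GeneSignature]:
    """The six built-in T-cell signatures (canonical HGNC symbols)."""
    plus = lambda *genes: tuple((g, +1) for g in genes)
    return [
        GeneSignature("stem_like_til", plus("TCF7", "IL7R", "CXCR5", "CD28", "CD27")),
        GeneSignature("trm", plus("CD69", "ITGAE")),
        GeneSignature("apa", plus("PDCD1", "CD27", "CD28", "TNFRSF9", "TNFRSF18")),
        GeneSignature(
            "early_dys",
            (("PDCD1", +1), ("CCR5", +1), ("TCF7", +1), ("HAVCR2", -1)),
        ),
        GeneSignature("late_dys", plus("PDCD1", "CD38", "ENTPD1", "CD101", "HAVCR2")),
        GeneSignature("btn3a", plus("BTN3A1", "BTN3A2", "BTN3A3")),
    ]


def signature_gene_union(sigs: list[GeneSignature] | None = None) -> list[str]:
    """Distinct marker genes across signatures, in first-seen order."""
    if sigs is None:
        sigs = builtin_signatures()
    seen: dict[str, None] = {}
    for sig in sigs:
        for g in sig.genes:
            seen.setdefault(g)
    return list(seen)


def load_signatures_yaml(path) -> list[GeneSignature]:
    """Read signatures from YAML: a list of {name, markers: [{gene, sign}]}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sigs = []
    for entry in raw:
        markers = tuple(
            (str(m["gene"]), int(m.get("sign", 1))) for m in entry["markers"]
        )
        sigs.append(GeneSignature(name=str(entry["name"]), markers=markers))
    return sigs


def save_signatures_yaml(sigs: list[GeneSignature], path) -> None:
    raw = [
        {
            "name": s.name,
            "markers": [{"gene": g, "sign": sign} for g, sign in s.markers],
        }
        for s in sigs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Sign-aware average z-score signature scoring (sklearn transformer).

    ``fit`` learns per-gene mean and SD (n-1 denominator) over the
    reference population; ``transform`` standardizes each marker gene and
    averages the signed z-scores per signature.  Input is samples x genes;
    output is a samples x signatures DataFrame in z-units.

    Parameters
    ----------
    signatures : list of GeneSignature, optional
        Defaults to the six built-in panels.
    strict : bool
        If True (default), missing marker genes raise; otherwise they are
        dropped with a warning and the average runs over the rest.
    """

    def __init__(self, signatures=None, strict: bool = True):
        self.signatures = signatures
        self.strict = strict

    def _sigs(self) -> list[GeneSignature]:
        return list(self.signatures) if self.signatures is not None else builtin_signatures()

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("reference population must have >= 2 samples")
        if X.columns.has_duplicates:
            raise ValueError("duplicate gene columns")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0).to_numpy(dtype=float)
        self.scale_ = X.std(axis=0, ddof=1).to_numpy(dtype=float)
        zero = self.scale_ == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance gene(s) score as z=0"
            )
        self.zero_variance_genes_ = [
            str(g) for g, z in zip(X.columns, zero) if z
        ]
        self.signatures_ = self._sigs()
        for sig in self.signatures_:
            missing = [g for g in sig.genes if g not in set(X.columns)]
            if missing and self.strict:
                raise ValueError(
                    f"signature {sig.name!r} markers missing from the "
                    f"matrix: {missing}"
                )
            if missing:
                warnings.warn(
                    f"signature {sig.name!r}: dropping missing markers {missing}"
                )
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "mean_"):
            raise ValueError("SignatureScorer is not fitted")
        X = pd.DataFrame(X)
        col_idx = {g: i for i, g in enumerate(self.feature_names_in_)}
        values = X.loc[:, self.feature_names_in_].to_numpy(dtype=float)
        safe_scale = np.where(self.scale_ == 0, 1.0, self.scale_)
        z = (values - self.mean_) / safe_scale
        z[:, self.scale_ == 0] = 0.0
        out = {}
        for sig in self.signatures_:
            pairs = [(col_idx[g], s) for g, s in sig.markers if g in col_idx]
            if not pairs:
                raise ValueError(f"signature {sig.name!r} has no usable markers")
            cols = np.array([i for i, _ in pairs])
            signs = np.array([s for _, s in pairs], dtype=float)
            out[sig.name] = (z[:, cols] * signs).mean(axis=1)
        return pd.DataFrame(out, index=X.index)


# ---------------------------------------------------------------------------
# functional wrappers on the genes x samples orientation
# ---------------------------------------------------------------------------


def _reference_columns(m: ExpressionMatrix, population) -> list[str]:
    if isinstance(population, str) and population == "all":
        return m.sample_ids
    population = list(population)
    missing = [s for s in population if s not in set(m.sample_ids)]
    if missing:
        raise ValueError(f"reference samples not in matrix: {missing}")
    return population


def gene_zscores(m: ExpressionMatrix, population="all") -> pd.DataFrame:
    """Per-gene z-scores (genes x samples) against a reference population.

    ``population`` is "all" or a list of sample IDs whose mean/SD define
    the standardization; all samples are then scored on that axis.
    Zero-variance genes yield an all-zero row.
    """
    if m.scale != SCALE_LOG:
        raise ValueError("gene_zscores expects log2(TPM+1) input")
    ref = _reference_columns(m, population)
    if len(ref) < 2:
        raise ValueError("reference population must have >= 2 samples")
    ref_vals = m.values[ref]
    mean = ref_vals.mean(axis=1)
    sd = ref_vals.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance gene(s) score as z=0")
    safe = sd.where(~zero, 1.0)
    z = m.values.sub(mean, axis=0).div(safe, axis=0)
    z.loc[zero] = 0.0
    return z


def score_signature(
    z: pd.DataFrame, sig: GeneSignature, strict: bool = True
) -> pd.Series:
    """Per-sample signed average of marker z-scores for one signature."""
    present = [pair for pair in sig.markers if pair[0] in z.index]
    missing = [g for g, _ in sig.markers if g not in z.index]
    if missing and strict:
        raise ValueError(
            f"signature {sig.name!r} markers missing from the matrix: {missing}"
        )
    if missing:
        warnings.warn(f"signature {sig.name!r}: dropping missing markers {missing}")
    if not present:
        raise ValueError(f"signature {sig.name!r} has no usable markers")
    signs = np.array([s for _, s in present], dtype=float)
    block = z.loc[[g for g, _ in present]].to_numpy()
    return pd.Series(
        (block * signs[:, None]).mean(axis=0), index=z.columns, name=sig.name
    )


def score_all(
    m: ExpressionMatrix,
    sigs: list[GeneSignature] | None = None,
    population="all",
    strict: bool = True,
) -> pd.DataFrame:
    """Samples x signatures table of average z-scores."""
    ref = _reference_columns(m, population)
    scorer = SignatureScorer(signatures=sigs, strict=strict)
    scorer.fit(m.values[ref].T)
    return scorer.transform(m.values.T)
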