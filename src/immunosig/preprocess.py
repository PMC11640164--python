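"""Expression-matrix I/O, scale handling, gene-ID standardization and
parametric empirical-Bayes batch adjustment.

Expression is carried as a genes x samples table with an explicit scale tag
(``"tpm"`` or ``"log2tpm1"``); every statistical stage of the package works
on the log2(TPM+1) scale.  Batch adjustment is the classical location/scale
empirical-Bayes procedure (ComBat): per-gene standardization, per-batch
location and scale estimates, shrinkage of those estimates toward
moment-matched normal / inverse-gamma priors via a fixed-point iteration,
then removal of the shrunken effects and restoration of the original
per-gene grand mean and pooled variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "log_transform",
    "DEFAULT_ALIASES",
    "standardize_gene_ids",
    "combat_adjust",
    "CombatAdjuster",
]

SCALE_TPM = "tpm"
SCALE_LOG = "log2tpm1"

#: Aliases for the marker genes used by the built-in signatures. Protein
#: names from the immunology literature are mapped to the canonical HGNC
#: symbol used in expression matrices; canonical symbols map to themselves.
DEFAULT_ALIASES: dict[str, str] = {
    "PD-1": "PDCD1",
    "PD1": "PDCD1",
    "TIM-3": "HAVCR2",
    "TIM3": "HAVCR2",
    "CD103": "ITGAE",
    "CD137": "TNFRSF9",
    "GITR": "TNFRSF18",
    "CD39": "ENTPD1",
    "PDCD1": "PDCD1",
    "HAVCR2": "HAVCR2",
    "ITGAE": "ITGAE",
    "TNFRSF9": "TNFRSF9",
    "TNFRSF18": "TNFRSF18",
    "ENTPD1": "ENTPD1",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with an explicit scale tag."""

    values: pd.DataFrame
    scale: str = SCALE_LOG

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_TPM, SCALE_LOG):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite (no missing)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression(path, scale: str = SCALE_LOG) -> ExpressionMatrix:
    """Read a TSV with gene IDs in the first column and sample-ID header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in expression file {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression file {path}: {exc}")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, scale=scale)


def write_expression(m: ExpressionMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """x -> log2(x + 1), TPM scale to log2(TPM+1) scale."""
    if m.scale == SCALE_LOG:
        raise ValueError("matrix is already on the log2(TPM+1) scale")
    arr = m.values.to_numpy()
    if np.any(arr < 0):
        raise ValueError("negative TPM value encountered")
    out = pd.DataFrame(
        np.log2(arr + 1.0), index=m.values.index, columns=m.values.columns
    )
    return ExpressionMatrix(values=out, scale=SCALE_LOG)


def standardize_gene_ids(
    m: ExpressionMatrix, aliases: Mapping[str, str] | None = None
) -> tuple[ExpressionMatrix, list[str]]:
    """Map gene IDs to canonical symbols; unmapped IDs pass through.

    Returns the renamed matrix and the list of IDs that had no alias entry
    (kept verbatim). Two rows collapsing onto one canonical ID is an error.
    """
    if aliases is None:
        aliases = DEFAULT_ALIASES
    canon = set(aliases.values())
    for c in canon:
        if aliases.get(c, c) != c:
            raise ValueError(f"canonical ID {c!r} does not map to itself")
    new_ids = [aliases.get(g, g) for g in m.gene_ids]
    unmapped = [g for g in m.gene_ids if g not in aliases]
    counts = pd.Series(new_ids).value_counts()
    collisions = counts[counts > 1].index.tolist()
    if collisions:
        raise ValueError(
            f"gene rows collapse onto the same canonical ID: {collisions}"
        )
    out = m.values.copy()
    out.index = pd.Index(new_ids, name=m.values.index.name)
    return ExpressionMatrix(values=out, scale=m.scale), unmapped


# ---------------------------------------------------------------------------
# parametric empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_fixed_point(
    s_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the coupled shrinkage equations for one batch.

    ``s_batch`` is genes x n_i standardized data; returns the shrunken
    per-gene location (gamma*) and scale (delta2*) estimates.
    """
    n = s_batch.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        sum2 = ((s_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


@dataclass
class _CombatParams:
    batches: list[str]
    grand_mean: np.ndarray          # per adjusted gene
    var_pooled: np.ndarray          # per adjusted gene
    gamma_star: dict[str, np.ndarray]
    delta_star: dict[str, np.ndarray]
    recenter: np.ndarray            # per-gene shift restoring the grand mean
    adjusted_mask: np.ndarray       # over all genes
    skipped_genes: list[str] = field(default_factory=list)


def _combat_fit_transform(
    values: np.ndarray,
    batch_labels: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, _CombatParams]:
    """Core adjustment on a genes x samples array. Returns adjusted data."""
    batches = sorted(set(batch_labels))
    idx = {b: np.flatnonzero(batch_labels == b) for b in batches}
    for b, members in idx.items():
        if members.size < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    n = values.shape[1]

    batch_means = np.column_stack(
        [values[:, idx[b]].mean(axis=1) for b in batches]
    )
    weights = np.array([idx[b].size / n for b in batches])
    grand_mean = batch_means @ weights
    fitted = np.zeros_like(values)
    for j, b in enumerate(batches):
        fitted[:, idx[b]] = batch_means[:, [j]]
    var_pooled = ((values - fitted) ** 2).mean(axis=1)

    ok = var_pooled > 0
    adjusted = values.copy()
    params = _CombatParams(
        batches=batches,
        grand_mean=grand_mean[ok],
        var_pooled=var_pooled[ok],
        gamma_star={},
        delta_star={},
        recenter=np.zeros(int(ok.sum())),
        adjusted_mask=ok,
    )
    if not ok.any():
        return adjusted, params

    v = values[ok]
    sd = np.sqrt(var_pooled[ok])
    s_data = (v - grand_mean[ok][:, None]) / sd[:, None]

    bayes = np.empty_like(s_data)
    for b in batches:
        members = idx[b]
        s_b = s_data[:, members]
        gamma_hat = s_b.mean(axis=1)
        delta_hat = s_b.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        a = _aprior(delta_hat)
        bp = _bprior(delta_hat)
        g_star, d_star = _eb_fixed_point(
            s_b, gamma_hat, delta_hat, gamma_bar, tau2, a, bp, tol, max_iter
        )
        params.gamma_star[b] = g_star
        params.delta_star[b] = d_star
        bayes[:, members] = (s_b - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = bayes * sd[:, None] + grand_mean[ok][:, None]
    # restore the per-gene grand mean exactly (shrinkage leaves a small
    # residual offset otherwise)
    recenter = grand_mean[ok] - out.mean(axis=1)
    out += recenter[:, None]
    params.recenter = recenter
    adjusted[ok] = out
    return adjusted, params


class CombatAdjuster(BaseEstimator, TransformerMixin):
    """Empirical-Bayes batch-effect removal as a sklearn transformer.

    Operates on samples x genes frames (sklearn orientation).  ``fit``
    estimates the standardization constants and the shrunken per-batch
    location/scale effects on the training data; ``transform`` removes them.
    With a single batch the transformer is a pass-through.

    Parameters
    ----------
    batches : array-like of shape (n_samples,), optional
        Batch label per sample; may instead be passed to ``fit``.
    tol : float
        Relative-change tolerance of the shrinkage fixed point.
    max_iter : int
        Iteration cap for the fixed point.
    """

    def __init__(self, batches=None, tol: float = 1e-6, max_iter: int = 500):
        self.batches = batches
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, batches=None):
        self.fit_transform(X, y, batches=batches)
        return self

    def fit_transform(self, X, y=None, batches=None):
        X = pd.DataFrame(X)
        labels = batches if batches is not None else self.batches
        if labels is None:
            raise ValueError("batch labels are required")
        labels = np.asarray(list(labels), dtype=object)
        if labels.size != X.shape[0]:
            raise ValueError("one batch label per sample is required")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        values = X.to_numpy(dtype=float).T  # genes x samples
        if len(set(labels)) < 2:
            self.params_ = None
            self.zero_variance_genes_ = []
            return X.copy()
        adjusted, params = _combat_fit_transform(
            values, labels, self.tol, self.max_iter
        )
        skipped = [
            str(g)
            for g, ok in zip(X.columns, params.adjusted_mask)
            if not ok
        ]
        params.skipped_genes = skipped
        if skipped:
            warnings.warn(
                f"{len(skipped)} zero-variance gene(s) passed through "
                f"unadjusted: {skipped[:5]}{'...' if len(skipped) > 5 else ''}"
            )
        self.params_ = params
        self.zero_variance_genes_ = skipped
        return pd.DataFrame(adjusted.T, index=X.index, columns=X.columns)

    def transform(self, X, batches=None):
        """Apply the fitted per-batch corrections to new samples."""
        if not hasattr(self, "params_"):
            raise ValueError("CombatAdjuster is not fitted")
        X = pd.DataFrame(X)
        if self.params_ is None:  # single batch at fit time
            return X.copy()
        labels = batches if batches is not None else self.batches
        if labels is None:
            raise ValueError("batch labels are required")
        labels = np.asarray(list(labels), dtype=object)
        p = self.params_
        values = X.to_numpy(dtype=float).T
        ok = p.adjusted_mask
        sd = np.sqrt(p.var_pooled)
        out = values.copy()
        for b in set(labels):
            if b not in p.gamma_star:
                raise ValueError(f"unseen batch label {b!r}")
            members = np.flatnonzero(labels == b)
            s = (values[ok][:, members] - p.grand_mean[:, None]) / sd[:, None]
            s = (s - p.gamma_star[b][:, None]) / np.sqrt(p.delta_star[b])[:, None]
            block = s * sd[:, None] + p.grand_mean[:, None] + p.recenter[:, None]
            sub = out[ok]
            sub[:, members] = block
            out[ok] = sub
        return pd.DataFrame(out.T, index=X.index, columns=X.columns)


def combat_adjust(
    m: ExpressionMatrix,
    batches: Mapping[str, str] | pd.Series,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ExpressionMatrix:
    """Adjust a log2(TPM+1) matrix for batch effects.

    ``batches`` maps sample ID to batch label and must cover every sample.
    A single batch is a pass-through; every batch needs >= 2 samples.
    Genes with zero pooled variance are passed through with a warning.
    """
    if m.scale != SCALE_LOG:
        raise ValueError("combat_adjust expects log2(TPM+1) input")
    labels = [batches[s] for s in m.sample_ids]
    adjuster = CombatAdjuster(tol=tol, max_iter=max_iter)
    adjusted = adjuster.fit_transform(m.values.T, batches=labels)
    return ExpressionMatrix(values=adjusted.T, scale=SCALE_LOG)
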