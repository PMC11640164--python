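"""Rank and survival statistics implemented from first principles.

The statistical kernel used throughout the package: Mann-Whitney U with an
exact enumeration mode and a tie-corrected normal approximation,
Benjamini-Hochberg FDR adjustment, rank AUROC, the Kaplan-Meier
product-limit estimator, the two-group log-rank test, and quantile-based
high/low splitting.  All of these are deliberately self-contained (numpy
only) so that the established library implementations can serve as
independent cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RankTestResult",
    "mann_whitney_u",
    "bh_adjust",
    "auroc",
    "KaplanMeierCurve",
    "km_fit",
    "LogrankResult",
    "logrank_test",
    "median_split",
    "chi2_sf_1df",
]

#: largest per-group size for which ``method="auto"`` uses exact enumeration
EXACT_THRESHOLD = 8


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _midranks(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (1-based, ties get the average of their rank span)."""
    _, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    # average rank of the tie group ending at cumulative position csum
    csum = np.cumsum(counts)
    avg = csum - (counts - 1) / 2.0
    return avg[inverse]


@dataclass(frozen=True)
class RankTestResult:
    """Result of a two-sample Mann-Whitney U test."""

    u_statistic: float
    p_two_sided: float
    n_a: int
    n_b: int
    method: str  # "exact" | "normal_approx"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n_a = a.size
    u = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    return u, ranks


def _exact_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided permutation-exact p by full enumeration of group assignments.

    Enumerates all C(n, n_a) assignments of the pooled mid-ranks to group A,
    takes the smaller tail probability of the observed U and doubles it.
    Valid in the presence of ties because the enumeration is over the
    observed (mid-ranked) data, i.e. it is the exact permutation null.
    """
    n = ranks.size
    offset = n_a * (n_a + 1) / 2.0
    n_le = 0
    n_ge = 0
    total = 0
    eps = 1e-9
    for idx in itertools.combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
        total += 1
    one_sided = min(n_le, n_ge) / total
    return min(1.0, 2.0 * one_sided)


def _normal_approx_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = ranks.size
    n_b = n - n_a
    mu = n_a * n_b / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0  # all observations tied
    z = max(0.0, abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    return min(1.0, math.erfc(z / math.sqrt(2.0)))


def mann_whitney_u(a, b, method: str = "auto") -> RankTestResult:
    """Two-sided Mann-Whitney U test with mid-rank tie handling.

    Parameters
    ----------
    a, b : array-like
        Score vectors for the two groups (each non-empty, finite).
    method : {"auto", "exact", "asymptotic"}
        "exact" enumerates all group assignments (permutation-exact, also
        valid with ties); "asymptotic" uses the tie-corrected normal
        approximation with continuity correction; "auto" picks exact when
        both groups have at most ``EXACT_THRESHOLD`` observations.
    """
    a = _as_1d_float(a, "a")
    b = _as_1d_float(b, "b")
    u_obs, ranks = _u_statistic(a, b)
    if method == "auto":
        method = "exact" if max(a.size, b.size) <= EXACT_THRESHOLD else "asymptotic"
    if method == "exact":
        p = _exact_p(ranks, a.size, u_obs)
        used = "exact"
    elif method == "asymptotic":
        p = _normal_approx_p(ranks, a.size, u_obs)
        used = "normal_approx"
    else:
        raise ValueError(f"unknown method {method!r}")
    return RankTestResult(
        u_statistic=float(u_obs),
        p_two_sided=float(p),
        n_a=a.size,
        n_b=b.size,
        method=used,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the
    original order of ``p``.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def auroc(pos, neg) -> float:
    """Rank AUROC: P(pos > neg) + 0.5 P(pos = neg) = U / (n_pos * n_neg)."""
    pos = _as_1d_float(pos, "pos")
    neg = _as_1d_float(neg, "neg")
    u, _ = _u_statistic(pos, neg)
    return float(u / (pos.size * neg.size))


def _check_survival_input(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = _as_1d_float(times, "times")
    events = np.asarray(events).ravel()
    if events.size != times.size:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    ev = events.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValueError("event indicators must be 0 or 1")
    return times, ev.astype(int)


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit estimate over the distinct event times.

    ``times`` are the distinct times at which at least one event occurred;
    subjects censored at an event time are still counted at risk for it.
    """

    times: np.ndarray      # distinct event times, increasing
    n_risk: np.ndarray     # at-risk counts just before each event time
    n_events: np.ndarray   # events at each time
    survival: np.ndarray   # S(t_i), non-increasing, S before first event = 1
    n_total: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def km_fit(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times, events = _check_survival_input(times, events)
    event_times = np.unique(times[events == 1])
    n_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    n_events = np.array(
        [((times == t) & (events == 1)).sum() for t in event_times], dtype=int
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - n_events / n_risk
    survival = np.cumprod(factors) if event_times.size else np.empty(0)
    return KaplanMeierCurve(
        times=event_times,
        n_risk=n_risk,
        n_events=n_events,
        survival=survival,
        n_total=times.size,
    )


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float


def chi2_sf_1df(x: float) -> float:
    """Survival function of chi-square with 1 df: erfc(sqrt(x/2))."""
    if x < 0:
        raise ValueError("chi2 statistic must be non-negative")
    return math.erfc(math.sqrt(x / 2.0))


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test.

    At each distinct pooled event time the observed events in group A are
    compared with their hypergeometric expectation; the statistic is
    (sum O - sum E)^2 / sum V with a chi-square(1) reference. Degenerate
    risk sets (sum V = 0) return chi2 = 0, p = 1.
    """
    ta, ea = _check_survival_input(times_a, events_a)
    tb, eb = _check_survival_input(times_b, events_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & group_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return LogrankResult(chi2=0.0, p=1.0)
    chi2 = o_minus_e**2 / var
    return LogrankResult(chi2=float(chi2), p=float(chi2_sf_1df(chi2)))


def median_split(scores, quantile: float = 0.5) -> np.ndarray:
    """Label each score "high" if strictly above the quantile cut, else "low".

    The default 0.5 quantile is a median split; scores equal to the cut are
    labelled low, so an all-tied input is all-low.
    """
    scores = _as_1d_float(scores, "scores")
    if scores.size < 2:
        raise ValueError("median_split requires at least 2 samples")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    cut = np.quantile(scores, quantile)
    return np.where(scores > cut, "high", "low")
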