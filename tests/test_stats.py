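"""Unit and property tests for the rank/survival statistics kernel.

Independent oracles: brute-force enumeration written here from pairwise
comparisons (a different route than the implementation's rank sums),
scipy.stats, statsmodels, sklearn.metrics and lifelines.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunosig import stats

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def u_by_pair_counting(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def exact_p_oracle(a, b) -> float:
    """Enumerate group assignments; U via pairwise comparison counting."""
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, len(a)
    u_obs = u_by_pair_counting(a, b)
    us = []
    for comb in itertools.combinations(range(n), n_a):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        us.append(u_by_pair_counting(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    eps = 1e-9
    le = np.mean(us <= u_obs + eps)
    ge = np.mean(us >= u_obs - eps)
    return min(1.0, 2.0 * min(le, ge))


def bh_oracle(p):
    """Literal double-loop step-up: q_i = min over j with p_j >= p_i ranked."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos in range(m):
        candidates = []
        for later in range(pos, m):
            candidates.append(p[order[later]] * m / (later + 1))
        q[order[pos]] = min(1.0, min(candidates))
    return q


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_worked_example(self):
        res = stats.mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 0.0
        assert res.p_two_sided == pytest.approx(1 / 3, abs=1e-12)
        assert res.method == "exact"

    def test_identical_groups_give_p_one(self):
        a = [1.0, 2.0, 2.0, 5.0]
        res = stats.mann_whitney_u(a, a)
        assert res.p_two_sided == 1.0
        assert res.u_statistic == len(a) ** 2 / 2

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 5, size=rng.integers(2, 7)).astype(float)
            b = rng.integers(0, 5, size=rng.integers(2, 7)).astype(float)
            r1 = stats.mann_whitney_u(a, b)
            r2 = stats.mann_whitney_u(b, a)
            assert r1.u_statistic + r2.u_statistic == pytest.approx(
                len(a) * len(b)
            )
            assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(1, 9))
        n_b = int(rng.integers(1, 9))
        # integer draws create ties with high probability
        a = rng.integers(0, 6, size=n_a).astype(float)
        b = rng.integers(0, 6, size=n_b).astype(float)
        res = stats.mann_whitney_u(a, b, method="exact")
        assert res.p_two_sided == pytest.approx(exact_p_oracle(a, b), abs=1e-12)
        assert res.u_statistic == pytest.approx(u_by_pair_counting(a, b))

    def test_exact_matches_scipy_without_ties(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            ours = stats.mann_whitney_u(a, b, method="exact")
            ref = scipy_stats.mannwhitneyu(a, b, method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_converges_to_exact(self):
        # The inherent worst case of the continuity-corrected normal
        # approximation against the exact n=8/8 null is 0.0109 (at U=24).
        worst = 0.0
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1, size=8)
            pe = stats.mann_whitney_u(a, b, method="exact").p_two_sided
            pn = stats.mann_whitney_u(a, b, method="asymptotic").p_two_sided
            worst = max(worst, abs(pe - pn))
        assert worst < 0.011

    def test_asymptotic_matches_scipy_with_ties(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.integers(0, 10, size=30).astype(float)
            b = rng.integers(0, 10, size=25).astype(float)
            ours = stats.mann_whitney_u(a, b, method="asymptotic")
            ref = scipy_stats.mannwhitneyu(a, b, method="asymptotic")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_auto_switches_to_normal_for_large_groups(self):
        rng = np.random.default_rng(5)
        res = stats.mann_whitney_u(rng.normal(size=9), rng.normal(size=9))
        assert res.method == "normal_approx"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.01, 0.04], [0.02, 0.04]),
        ],
    )
    def test_hand_cases(self, p, expected):
        assert stats.bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 21)))
        assert stats.bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        p = rng.random(15)
        ref = sm.multipletests(p, method="fdr_bh")[1]
        assert stats.bh_adjust(p) == pytest.approx(ref, abs=1e-12)

    def test_monotone_in_order_statistics(self):
        rng = np.random.default_rng(7)
        p = rng.random(12)
        q = stats.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------


class TestAuroc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([5, 6], [1, 2], 1.0),
            ([1, 1], [1, 1], 0.5),
            ([3, 5], [1, 4], 0.75),
        ],
    )
    def test_hand_cases(self, pos, neg, expected):
        assert stats.auroc(pos, neg) == pytest.approx(expected)

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=12),
        st.lists(st.integers(0, 6), min_size=1, max_size=12),
    )
    @settings(derandomize=True, max_examples=60)
    def test_complement_symmetry(self, pos, neg):
        assert stats.auroc(pos, neg) + stats.auroc(neg, pos) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_pair_counting_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        for _ in range(20):
            pos = rng.integers(0, 8, size=15).astype(float)
            neg = rng.integers(0, 8, size=12).astype(float)
            ours = stats.auroc(pos, neg)
            assert ours == pytest.approx(
                u_by_pair_counting(pos, neg) / (15 * 12), abs=1e-12
            )
            y = np.r_[np.ones(15), np.zeros(12)]
            assert ours == pytest.approx(
                roc_auc_score(y, np.r_[pos, neg]), abs=1e-12
            )


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_events(self):
        km = stats.km_fit([1, 2, 3], [1, 1, 1])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censoring_shrinks_risk_set(self):
        km = stats.km_fit([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)
        assert km.n_risk.tolist() == [3, 1]

    def test_no_events_flat_curve(self):
        km = stats.km_fit([4, 5, 6], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at([0, 10]) == pytest.approx([1.0, 1.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, size=80)
        km = stats.km_fit(times, np.ones(80))
        for t in km.times:
            assert km.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(10)
        times = rng.exponential(20, size=60)
        events = rng.integers(0, 2, size=60)
        km = stats.km_fit(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        ref = kmf.survival_function_at_times(km.times).to_numpy()
        assert km.survival == pytest.approx(ref, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            stats.km_fit([-1, 2], [1, 1])
        with pytest.raises(ValueError):
            stats.km_fit([1, 2], [1, 2])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4.0]
        e = [1, 1, 0, 1]
        res = stats.logrank_test(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_hand_tabulated_worked_case(self):
        # A=[1,2] both events, B=[3,4] both events.
        # t=1: n=4, nA=2, d=1 -> E=0.5, V=0.25
        # t=2: n=3, nA=1, d=1 -> E=1/3, V=2/9
        # t=3,4: nA=0 or n=1 -> no variance contribution
        # O-E = 2 - 5/6, V = 17/36, chi2 = (7/6)^2/(17/36) = 49/17
        res = stats.logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.chi2 == pytest.approx(49 / 17, abs=1e-12)
        assert res.p == pytest.approx(stats.chi2_sf_1df(49 / 17), abs=1e-15)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(11)
        ta, tb = rng.exponential(10, 20), rng.exponential(14, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        r1 = stats.logrank_test(ta, ea, tb, eb)
        r2 = stats.logrank_test(tb, eb, ta, ea)
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(12)
        ta, tb = rng.exponential(10, 30), rng.exponential(20, 35)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 35)
        ours = stats.logrank_test(ta, ea, tb, eb)
        ref = lifelines_stats.logrank_test(ta, tb, ea, eb)
        assert ours.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_null_p_approximately_uniform(self):
        """Two groups from one survival law: p < 0.05 in about 5% of draws."""
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            t = rng.exponential(30, size=60)
            c = rng.uniform(0, 120, size=60)
            times = np.minimum(t, c)
            events = (t <= c).astype(int)
            res = stats.logrank_test(times[:30], events[:30], times[30:], events[30:])
            hits += res.p < 0.05
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) <= 3 * se


def test_chi2_sf_matches_scipy():
    scipy_stats = pytest.importorskip("scipy.stats")
    for x in [0.0, 0.3, 1.0, 2.88, 10.0, 30.0]:
        assert stats.chi2_sf_1df(x) == pytest.approx(
            scipy_stats.chi2.sf(x, df=1), rel=1e-12
        )


class TestMedianSplit:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([1, 2, 3, 4], ["low", "low", "high", "high"]),
            ([7, 7, 7], ["low", "low", "low"]),
            ([5, 1, 3], ["high", "low", "low"]),
        ],
    )
    def test_cases(self, scores, expected):
        assert stats.median_split(scores).tolist() == expected

    def test_quantile_split(self):
        labels = stats.median_split([1, 2, 3, 4, 5], quantile=0.8)
        assert labels.tolist() == ["low", "low", "low", "low", "high"]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            stats.median_split([1.0])
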