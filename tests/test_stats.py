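import itertools

import numpy as np
import pandas as pd
import pytest

from flyphen.errors import InvalidInputError, LookupError_
from flyphen.stats import (
    TestResult,
    km_estimate,
    logrank_test,
    pairwise_logrank_bonferroni,
    wilcoxon_rank_sum,
)


def table(groups_times_events):
    """Build a survival table from (group, time, event) triples."""
    rows = [
        {"subject_id": f"s{i}", "group": g, "time_days": t, "event": e}
        for i, (g, t, e) in enumerate(groups_times_events)
    ]
    return pd.DataFrame(rows)


def brute_force_logrank(times_a, events_a, times_b, events_b):
    """Oracle: explicit O, E, Var bookkeeping at every distinct event time."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    in_a = np.concatenate([np.ones(len(times_a), bool), np.zeros(len(times_b), bool)])
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        n = sum(times >= t)
        n_a = sum((times >= t) & in_a)
        d = sum((times == t) & (events == 1))
        d_a = sum((times == t) & (events == 1) & in_a)
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (o_minus_e**2 / var) if var > 0 else 0.0


def enumeration_ranksum_p(x, y):
    """Oracle: exact two-sided p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1  # tie-free by construction
    n_x = len(x)
    observed = ranks[:n_x].sum()
    mean_w = n_x * (len(pooled) + 1) / 2
    obs_dev = abs(observed - mean_w)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= obs_dev - 1e-9:
            count += 1
    return count / total


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        tab = table([("g", t, 0) for t in (1.0, 2.0, 3.0)])
        km = km_estimate(tab, "g")
        assert km(0.5) == 1.0
        assert km(10.0) == 1.0

    def test_three_events_product_limit(self):
        tab = table([("g", 1.0, 1), ("g", 2.0, 1), ("g", 3.0, 1)])
        km = km_estimate(tab, "g")
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.0) == pytest.approx(1 / 3)
        assert km(3.0) == pytest.approx(0.0)
        assert km(0.5) == 1.0

    def test_censoring_bookkeeping(self):
        # event at 1, censored at 2, event at 3:
        # S(1) = 2/3; at t=3 risk set is 1 -> S(3) = 2/3 * 0 = 0
        tab = table([("g", 1.0, 1), ("g", 2.0, 0), ("g", 3.0, 1)])
        km = km_estimate(tab, "g")
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.5) == pytest.approx(2 / 3)  # censoring leaves no step
        assert km(3.0) == pytest.approx(0.0)

    def test_reduces_to_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            times = rng.exponential(10, size=25).round(2) + 0.01
            tab = table([("g", t, 1) for t in times])
            km = km_estimate(tab, "g")
            grid = np.linspace(0.01, times.max() + 1, 50)
            ecdf_surv = [(times > t).mean() for t in grid]
            np.testing.assert_allclose(km(grid), ecdf_surv, atol=1e-12)

    def test_nonincreasing(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, size=40) + 0.01
        events = rng.integers(0, 2, size=40)
        tab = table([("g", t, e) for t, e in zip(times, events)])
        km = km_estimate(tab, "g")
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        times = rng.exponential(10, size=60).round(1) + 0.1
        events = rng.integers(0, 2, size=60)
        tab = table([("g", t, e) for t, e in zip(times, events)])
        km = km_estimate(tab, "g")
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        grid = np.linspace(0.1, times.max(), 30)
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(km(grid), theirs, atol=1e-10)

    def test_unknown_group(self):
        tab = table([("g", 1.0, 1)])
        with pytest.raises(LookupError_):
            km_estimate(tab, "nope")


class TestLogrank:
    def test_identical_groups(self):
        rows = [("a", t, 1) for t in (1.0, 2.0, 5.0)]
        tab = table(rows + [("b", t, e) for (_, t, e) in rows])
        res = logrank_test(tab, "a", "b")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_table_matches_brute_force(self):
        tab = table([("a", 1.0, 1), ("a", 2.0, 1), ("b", 3.0, 1), ("b", 4.0, 1)])
        res = logrank_test(tab, "a", "b")
        expected = brute_force_logrank(
            np.array([1.0, 2.0]), np.array([1, 1]),
            np.array([3.0, 4.0]), np.array([1, 1]),
        )
        assert res.statistic == pytest.approx(expected)

    def test_random_tables_match_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            na, nb = rng.integers(3, 15, size=2)
            ta = rng.exponential(5, na).round(1) + 0.1  # rounding forces ties
            tb = rng.exponential(8, nb).round(1) + 0.1
            ea = rng.integers(0, 2, na)
            eb = rng.integers(0, 2, nb)
            tab = table(
                [("a", t, e) for t, e in zip(ta, ea)]
                + [("b", t, e) for t, e in zip(tb, eb)]
            )
            res = logrank_test(tab, "a", "b")
            assert res.statistic == pytest.approx(
                brute_force_logrank(ta, ea, tb, eb), abs=1e-10
            )

    def test_all_censored(self):
        tab = table([("a", 1.0, 0), ("a", 2.0, 0), ("b", 3.0, 0)])
        res = logrank_test(tab, "a", "b")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(5, 10) + 0.1, rng.exponential(9, 12) + 0.1
        tab = table(
            [("a", t, 1) for t in ta] + [("b", t, 1) for t in tb]
        )
        assert logrank_test(tab, "a", "b").statistic == pytest.approx(
            logrank_test(tab, "b", "a").statistic
        )

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(5)
        ta, tb = rng.exponential(5, 10) + 0.1, rng.exponential(9, 12) + 0.1
        ea = rng.integers(0, 2, 10)
        eb = rng.integers(0, 2, 12)
        tab1 = table(
            [("a", t, e) for t, e in zip(ta, ea)]
            + [("b", t, e) for t, e in zip(tb, eb)]
        )
        tab2 = table(
            [("a", np.exp(t / 10), e) for t, e in zip(ta, ea)]
            + [("b", np.exp(t / 10), e) for t, e in zip(tb, eb)]
        )
        assert logrank_test(tab1, "a", "b").statistic == pytest.approx(
            logrank_test(tab2, "a", "b").statistic
        )

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(6)
        ta, tb = rng.exponential(5, 30).round(1) + 0.1, rng.exponential(9, 25).round(1) + 0.1
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
        tab = table(
            [("a", t, e) for t, e in zip(ta, ea)]
            + [("b", t, e) for t, e in zip(tb, eb)]
        )
        ours = logrank_test(tab, "a", "b")
        theirs = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert ours.statistic == pytest.approx(theirs.test_statistic, abs=1e-8)
        assert ours.p_value == pytest.approx(theirs.p_value, abs=1e-8)

    def test_missing_group_rejected(self):
        tab = table([("a", 1.0, 1)])
        with pytest.raises(InvalidInputError):
            logrank_test(tab, "a", "b")


class TestPairwiseBonferroni:
    def _multi_group_table(self, k, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(k):
            for t in rng.exponential(5 + g, 12):
                rows.append((f"g{g}", t + 0.1, 1))
        return table(rows)

    def test_two_groups_factor_one(self):
        tab = self._multi_group_table(2)
        out = pairwise_logrank_bonferroni(tab)
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_value"].iloc[0])

    def test_four_groups_six_pairs(self):
        out = pairwise_logrank_bonferroni(self._multi_group_table(4))
        assert len(out) == 6
        assert (out["n_pairs"] == 6).all()
        for _, row in out.iterrows():
            assert row["p_adjusted"] == pytest.approx(
                min(1.0, row["p_value"] * 6)
            )

    def test_adjustment_caps_at_one(self):
        out = pairwise_logrank_bonferroni(self._multi_group_table(4, seed=1))
        big = out[out["p_value"] > 1 / 6]
        assert (big["p_adjusted"] == 1.0).all()
        assert len(big) > 0

    def test_single_group_rejected(self):
        with pytest.raises(InvalidInputError):
            pairwise_logrank_bonferroni(table([("a", 1.0, 1), ("a", 2.0, 1)]))


class TestWilcoxon:
    def test_two_vs_two_exact(self):
        res = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert res.p_value == pytest.approx(2 / 6)
        assert "exact" in res.method

    def test_identical_multisets(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_small(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            nx, ny = rng.integers(2, 7, size=2)
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # tie-free
            x, y = pooled[:nx], pooled[nx:]
            res = wilcoxon_rank_sum(x, y)
            assert "exact" in res.method
            assert res.p_value == pytest.approx(enumeration_ranksum_p(x, y))

    def test_ties_fall_back_to_asymptotic(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert "asymptotic" in res.method

    def test_large_samples_asymptotic(self):
        rng = np.random.default_rng(8)
        res = wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
        assert "asymptotic" in res.method
        assert 0 < res.p_value <= 1

    def test_statistic_is_rank_sum_with_midranks(self):
        res = wilcoxon_rank_sum([1.0, 3.0, 3.0], [3.0, 5.0])
        # ranks: 1, midrank 3 for the three 3.0s, 5 -> W_x = 1 + 3 + 3
        assert res.statistic == pytest.approx(7.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            wilcoxon_rank_sum([], [1.0])


class TestTestResult:
    def test_p_adjusted_cannot_undercut_p(self):
        with pytest.raises(InvalidInputError):
            TestResult(
                statistic=1.0, p_value=0.5, method="m",
                n_per_group=(2, 2), p_adjusted=0.1,
            )

    def test_p_range_enforced(self):
        with pytest.raises(InvalidInputError):
            TestResult(statistic=1.0, p_value=1.5, method="m", n_per_group=(2,))
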