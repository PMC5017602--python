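"""Kaplan-Meier, log-rank and Fisher's exact tests, cross-checked against
lifelines and scipy."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from stagescan import (
    ClusterAssignment,
    OutcomeRecord,
    compare_clusters,
    fisher_exact,
    km_estimate,
    logrank_test,
)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate([1, 2, 3, 4], [True] * 4)
        assert np.allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([1, 2, 3], [False] * 3)
        assert curve.event_times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_product_limit_hand_calculation(self):
        # {1, 2+, 3}: S(1) = 2/3; S(3) = 2/3 * (1 - 1/1) = 0
        curve = km_estimate([1, 2, 3], [True, False, True])
        assert np.allclose(curve.event_times, [1, 3])
        assert curve.survival[0] == pytest.approx(2 / 3)
        assert curve.survival[1] == pytest.approx(0.0)

    def test_censoring_at_event_time_keeps_subject_at_risk(self):
        # at t=2 one event among 3 at risk (the censored subject counts)
        curve = km_estimate([1, 2, 2, 3], [True, True, False, True])
        assert curve.survival[1] == pytest.approx(0.75 * (1 - 1 / 3))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(100, size=60)
        events = rng.random(60) < 0.7
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_no_censoring_matches_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(50, size=40)
        curve = km_estimate(times, [True] * 40)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = ([1, 2, 3], [True, True, True])
        res = logrank_test([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_group_swap_invariance(self):
        rng = np.random.default_rng(0)
        a = (rng.exponential(50, 20), rng.random(20) < 0.8)
        b = (rng.exponential(120, 20), rng.random(20) < 0.8)
        assert logrank_test([a, b]).statistic == pytest.approx(
            logrank_test([b, a]).statistic, rel=1e-10
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_group_matches_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        ta, tb = rng.exponential(60, 25), rng.exponential(100, 30)
        ea, eb = rng.random(25) < 0.75, rng.random(30) < 0.75
        res = logrank_test([(ta, ea), (tb, eb)])
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert res.p == pytest.approx(ref.p_value, rel=1e-8)

    def test_three_group_matches_lifelines(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(80, 60)
        events = rng.random(60) < 0.8
        labels = np.repeat([0, 1, 2], 20)
        res = logrank_test(
            [(times[labels == g], events[labels == g]) for g in (0, 1, 2)]
        )
        ref = multivariate_logrank_test(times, labels, events)
        assert res.df == 2
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert res.p == pytest.approx(ref.p_value, rel=1e-8)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([([1, 2], [False, False]), ([3], [False])])

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            logrank_test([([1, 2], [True, True]), ([], [])])


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_all_zero_row_p_one(self):
        assert fisher_exact([[0, 0], [7, 3]]) == pytest.approx(1.0)

    def test_hand_checked_table(self):
        # independently checked against the full hypergeometric enumeration
        assert fisher_exact([[1, 9], [11, 3]]) == pytest.approx(
            stats.fisher_exact([[1, 9], [11, 3]])[1], rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_random_2x2_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 15, size=(2, 2))
        if table.sum() == 0:
            table[0, 0] = 1
        assert fisher_exact(table) == pytest.approx(
            stats.fisher_exact(table)[1], rel=1e-9
        )

    def test_2x4_matches_2x2_collapse_consistency(self):
        # Freeman-Halton on a 2x4 with two empty columns reduces to the 2x2
        p_2x4 = fisher_exact([[3, 7, 0, 0], [8, 2, 0, 0]])
        p_2x2 = fisher_exact([[3, 7], [8, 2]])
        assert p_2x4 == pytest.approx(p_2x2, rel=1e-12)

    def test_2x3_uniformity(self):
        # symmetric 2x3 table is its own most likely configuration
        assert fisher_exact([[2, 2, 2], [2, 2, 2]]) == pytest.approx(1.0)

    def test_negative_count_errors(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_exact([[1, -1], [2, 3]])

    def test_wide_table_rejected(self):
        with pytest.raises(ValueError, match="k <= 4"):
            fisher_exact(np.ones((2, 5), dtype=int))


def _assignment(n_per_cluster: int) -> ClusterAssignment:
    patterns = {}
    layout = {
        1: (True, True, True),
        2: (True, False, False),
        3: (False, True, False),
        4: (False, False, False),
    }
    for cluster, pattern in layout.items():
        for i in range(n_per_cluster):
            patterns[f"c{cluster}_{i:03d}"] = pattern
    return ClusterAssignment.from_patterns(patterns)


class TestCompareClusters:
    def test_discriminating_outcomes_detected(self):
        from stagescan import CohortSpec, simulate_outcomes

        assignment = _assignment(40)
        records = simulate_outcomes(assignment, CohortSpec(seed=0))
        report = compare_clusters(assignment, records)
        assert set(report.mrd_table.index) == {1, 2, 3, 4}
        assert report.mrd_cluster1_vs_rest_p is not None
        assert report.mrd_overall_p <= 0.05
        assert {"efs", "os"} <= set(report.logrank_omnibus)
        assert (1, 3) in report.logrank_pairwise["efs"]

    def test_missing_outcomes_are_excluded(self):
        assignment = _assignment(3)
        records = [
            OutcomeRecord(mrd29_positive=bool(i % 2)) if i % 3 else None
            for i in range(12)
        ]
        report = compare_clusters(assignment, records)
        assert report.n_excluded["mrd29"] > 0
        assert report.logrank_omnibus == {}

    def test_single_cluster_errors(self):
        patterns = {f"s{i}": (True, True, True) for i in range(5)}
        assignment = ClusterAssignment.from_patterns(patterns)
        records = [OutcomeRecord(mrd29_positive=True)] * 5
        with pytest.raises(ValueError, match=">= 2 clusters"):
            compare_clusters(assignment, records)
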