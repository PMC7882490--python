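import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskbeliefs.benchmarks import compute_rates
from riskbeliefs.calibration import (
    classify_pairs,
    fold_difference,
    paired_test,
    proportional_slope,
    stratified_gap,
)


def frame(a, b, names=("q1_ifr", "q4_prevalence")):
    return pd.DataFrame({names[0]: a, names[1]: b})


class TestPairedTest:
    def test_identical_vectors_give_zero_t_unit_p(self):
        cmp = paired_test(frame([1, 2, 3], [1, 2, 3]), "q1_ifr", "q4_prevalence")
        assert cmp.mean_difference == 0.0
        assert cmp.t_statistic == 0.0
        assert cmp.p_value == 1.0

    def test_hand_computed_t_statistic(self):
        # d = {1,2,3}: mean 2, sd 1, n 3 -> t = 2*sqrt(3)
        cmp = paired_test(frame([1, 2, 3], [0, 0, 0]), "q1_ifr", "q4_prevalence")
        assert cmp.t_statistic == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert cmp.p_value == pytest.approx(0.0742, abs=2e-4)

    def test_listwise_deletion_of_incomplete_pairs(self):
        cmp = paired_test(
            frame([1, 2, np.nan, 4], [0, np.nan, 1, 2]), "q1_ifr", "q4_prevalence"
        )
        assert cmp.n_pairs == 2

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 100), st.integers(0, 100)), min_size=3, max_size=40
        ).filter(lambda v: len({a - b for a, b in v}) > 1)
    )
    def test_two_sided_p_is_twice_smaller_one_sided(self, pairs):
        a, b = zip(*pairs)
        df = frame(list(a), list(b))
        two = paired_test(df, "q1_ifr", "q4_prevalence", "two_sided").p_value
        lo = paired_test(df, "q1_ifr", "q4_prevalence", "one_sided_a_lt_b").p_value
        hi = paired_test(df, "q1_ifr", "q4_prevalence", "one_sided_a_gt_b").p_value
        assert two == pytest.approx(2 * min(lo, hi), abs=1e-10)

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError, match="complete pairs"):
            paired_test(frame([1], [2]), "q1_ifr", "q4_prevalence")


class TestClassifyPairs:
    def test_all_equal_when_identical(self):
        cls = classify_pairs(frame([3, 3, 3], [3, 3, 3]), "q1_ifr", "q4_prevalence")
        assert (cls.n_higher, cls.n_equal, cls.n_lower) == (0, 3, 0)

    def test_one_of_each(self):
        cls = classify_pairs(frame([5, 3, 1], [1, 3, 5]), "q1_ifr", "q4_prevalence")
        assert (cls.n_higher, cls.n_equal, cls.n_lower) == (1, 1, 1)

    def test_counts_sum_to_pairs_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 100, 200).astype(float)
        b = rng.integers(0, 100, 200).astype(float)
        cls = classify_pairs(frame(a, b), "q1_ifr", "q4_prevalence")
        assert cls.n_pairs == 200
        perm = rng.permutation(200)
        cls2 = classify_pairs(frame(a[perm], b[perm]), "q1_ifr", "q4_prevalence")
        assert cls == cls2

    def test_tolerance_widens_equality(self):
        df = frame([10, 12, 20], [11, 10, 10])
        strict = classify_pairs(df, "q1_ifr", "q4_prevalence", tolerance=0)
        loose = classify_pairs(df, "q1_ifr", "q4_prevalence", tolerance=2)
        assert strict.n_equal == 0
        assert loose.n_equal == 2


class TestProportionalSlope:
    def test_exact_proportionality_gives_zero_se(self):
        x = np.array([1.0, 2, 3, 4])
        for c in (0.5, 2.0, -1.3):
            slope, se = proportional_slope(
                frame(c * x, x, names=("q7_contagious", "q7bis_contagious_flu")),
                "q7_contagious",
                "q7bis_contagious_flu",
            )
            assert slope == pytest.approx(c)
            assert se == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_slope(self):
        # sum(xy) = 8, sum(x^2) = 5
        slope, _ = proportional_slope(
            frame([2, 3], [1, 2], names=("y", "x")), "y", "x"
        )
        assert slope == pytest.approx(1.6)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError, match="slope undefined"):
            proportional_slope(frame([1, 2], [0, 0], names=("y", "x")), "y", "x")


def test_fold_difference_of_reproduction_numbers():
    # quarantine-lowered R0 1.78 against seasonal influenza's 1.3
    assert round(fold_difference(1.78, 1.3), 2) == 1.37


class TestStratifiedGap:
    def _bench(self, prev_per100):
        counts = pd.DataFrame(
            {
                "region_tier": list(prev_per100),
                "deaths": 0,
                "diagnosed": [int(p * 10_000) for p in prev_per100.values()],
                "population": 1_000_000,
            }
        )
        return compute_rates(counts)

    def test_gap_arithmetic(self):
        df = pd.DataFrame({"region_tier": ["lowest"] * 3, "q2_own_risk": [34, 34, 34]})
        out = stratified_gap(df, "q2_own_risk", self._bench({"lowest": 0.05}), "region_tier")
        assert out.loc[0, "gap"] == pytest.approx(34 - 0.05)

    def test_stratum_absent_from_benchmark_flagged(self):
        df = pd.DataFrame(
            {"region_tier": ["lowest", "unknown"], "q2_own_risk": [30.0, 40.0]}
        )
        out = stratified_gap(
            df, "q2_own_risk", self._bench({"lowest": 0.05}), "region_tier"
        ).set_index("region_tier")
        assert not out.loc["unknown", "comparable"]
        assert np.isnan(out.loc["unknown", "gap"])

    def test_beliefs_generated_at_benchmark_give_zero_gap(self):
        rng = np.random.default_rng(8)
        prev = {"lowest": 25.0, "medium": 35.0, "highest": 45.0}
        rows = []
        for tier, p in prev.items():
            rows.append(
                pd.DataFrame(
                    {
                        "region_tier": tier,
                        "q2_own_risk": 100 * rng.beta(p / 100 * 50, (1 - p / 100) * 50, 2000),
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        out = stratified_gap(df, "q2_own_risk", self._bench(prev), "region_tier")
        assert np.abs(out["gap"]).max() < 1.0  # Monte-Carlo tolerance

    def test_increasing_belief_means_give_ordered_gaps(self):
        df = pd.DataFrame(
            {
                "region_tier": ["lowest"] * 5 + ["medium"] * 5 + ["highest"] * 5,
                "q2_own_risk": [20.0] * 5 + [40.0] * 5 + [60.0] * 5,
            }
        )
        bench = self._bench({"lowest": 1.0, "medium": 1.0, "highest": 1.0})
        out = stratified_gap(df, "q2_own_risk", bench, "region_tier").set_index("region_tier")
        assert out.loc["lowest", "gap"] < out.loc["medium", "gap"] < out.loc["highest", "gap"]
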