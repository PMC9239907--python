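"""Evaluation battery: concordance, resampling inference, Kaplan-Meier,
log-rank, threshold search, Kendall tau and the CRS association test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import harrell_c_pairs, km_product_limit, logrank_two_group
from conftest import random_survival
from mmsurv.evaluation import (
    DEFAULT_THRESHOLD_GRID,
    bootstrap_ci,
    crs_association,
    harrell_c,
    kendall_cross_modal,
    km_curve,
    logrank,
    median_survival,
    permutation_test,
    survival_at,
    threshold_search,
)


class TestHarrellC:
    def test_all_tied_scores_give_half(self):
        T = [5.0, 3.0, 8.0, 1.0]
        assert harrell_c([1, 1, 1, 1], T, [True] * 4) == 0.5

    def test_perfect_ordering(self):
        """Scores increasing with survival time -> c = 1 (higher score =
        longer survival under the negative-log-hazard convention)."""
        T = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrell_c(T, T, np.ones(4, bool)) == 1.0

    def test_two_of_three_pairs_concordant(self):
        # times (3,2,1), scores (2,3,1): of the three comparable pairs the
        # two involving the shortest survivor are concordant -> 2/3
        c = harrell_c([2.0, 3.0, 1.0], [3.0, 2.0, 1.0], [True] * 3)
        assert c == pytest.approx(2 / 3)

    def test_matches_pair_enumeration_on_random_censored_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 31)
            x, T, E = random_survival(rng, n, censor_frac=rng.uniform(0, 0.6))
            if not E.any():
                continue
            s = rng.normal(size=n)
            assert harrell_c(s, T, E) == pytest.approx(
                harrell_c_pairs(s, T, E), abs=1e-12
            )

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            harrell_c([1.0, 2.0], [5.0, 6.0], [False, False])


class TestBootstrapCI:
    def test_constant_risks_degenerate_interval(self):
        T = np.linspace(1, 20, 20)
        lo, hi = bootstrap_ci(np.ones(20), T, np.ones(20, bool), seed=0)
        assert (lo, hi) == (0.5, 0.5)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(1)
        x, T, E = random_survival(rng, 40, beta=0.5)
        assert bootstrap_ci(x, T, E, seed=7) == bootstrap_ci(x, T, E, seed=7)

    def test_many_rep_interval_brackets_few_rep_center(self):
        rng = np.random.default_rng(2)
        x, T, E = random_survival(rng, 80, beta=0.5)
        lo100, hi100 = bootstrap_ci(x, T, E, n_reps=100, seed=3)
        lo_big, hi_big = bootstrap_ci(x, T, E, n_reps=2000, seed=4)
        center = 0.5 * (lo100 + hi100)
        assert lo_big <= center <= hi_big

    def test_jackknife_mode(self):
        rng = np.random.default_rng(3)
        x, T, E = random_survival(rng, 30, beta=0.8)
        lo, hi = bootstrap_ci(x, T, E, method="jackknife")
        assert 0 <= lo <= hi <= 1


class TestPermutationTest:
    def test_constant_risks_p_one(self):
        T = np.linspace(1, 10, 10)
        assert permutation_test(np.ones(10), T, np.ones(10, bool), n_perm=50) == 1.0

    def test_perfectly_ordered_risks_significant(self):
        T = np.arange(1.0, 11.0)
        p = permutation_test(T, T, np.ones(10, bool), n_perm=1000, seed=0)
        assert p <= 0.01

    def test_p_never_zero(self):
        T = np.arange(1.0, 9.0)
        p = permutation_test(T, T, np.ones(8, bool), n_perm=100, seed=0)
        assert p >= 1 / 101


class TestKaplanMeier:
    def test_starts_at_one_and_single_event(self):
        curve = km_curve([10.0], [True])
        assert survival_at(curve, 0.0) == 1.0
        assert curve.survival[-1] == 0.0

    def test_matches_hand_product_limit(self):
        T = [1.0, 2.0, 2.5, 3.0]
        E = [True, True, False, True]
        curve = km_curve(T, E)
        times, surv = km_product_limit(T, E)
        for t, s in zip(times, surv):
            idx = np.searchsorted(curve.times, t)
            assert curve.survival[idx] == pytest.approx(s, abs=1e-12)

    def test_interpolation_linear_between_steps(self):
        curve = km_curve([2.0, 4.0], [True, True])
        # S(2)=0.5, S(4)=0 -> midpoint 3.0 interpolates to 0.25
        assert survival_at(curve, 3.0) == pytest.approx(0.25)

    def test_survival_monotone_non_increasing(self):
        rng = np.random.default_rng(5)
        _, T, E = random_survival(rng, 50)
        curve = km_curve(T, E)
        ts = np.linspace(0, T.max() * 1.2, 200)
        vals = [survival_at(curve, t) for t in ts]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] == 1.0

    def test_median_survival_interpolated(self):
        curve = km_curve([2.0, 4.0], [True, True])
        assert median_survival(curve) == pytest.approx(2.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(km_curve([1.0], [True]), -1.0)


class TestLogrank:
    def test_identical_groups_no_signal(self):
        T = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        E = [True] * 6
        g = ["a"] * 3 + ["b"] * 3
        stat, p = logrank(T, E, g)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p > 0.99

    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(8, 30))
            _, T, E = random_survival(rng, n)
            if not E.any():
                continue
            g = np.where(rng.random(n) < 0.5, "a", "b")
            if len(np.unique(g)) < 2:
                continue
            stat, _ = logrank(T, E, g)
            assert stat == pytest.approx(logrank_two_group(T, E, g), abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([1.0, 2.0], [True, True], ["a", "a"])


class TestThresholdSearch:
    def test_default_grid_is_33_to_66(self):
        assert len(DEFAULT_THRESHOLD_GRID) == 34
        assert DEFAULT_THRESHOLD_GRID[0] == 0.33
        assert DEFAULT_THRESHOLD_GRID[-1] == 0.66

    def test_single_point_grid_returned_unconditionally(self):
        rng = np.random.default_rng(7)
        x, T, E = random_survival(rng, 60, beta=0.8)
        rg = threshold_search(pd.Series(-x), T, E, grid=[0.5])
        assert rg.percentile == 0.5

    def test_median_split_signal_found_near_half(self):
        """When the true risk split is at the median, the chosen threshold
        concentrates near 0.50 (majority over seeds)."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 300
            high = np.arange(n) < n // 2
            T = rng.exponential(np.where(high, 10.0, 60.0))
            scores = pd.Series(np.where(high, 0.0, 1.0) + rng.normal(0, 0.01, n))
            rg = threshold_search(scores, T, np.ones(n, bool))
            hits += abs(rg.percentile - 0.5) <= 0.05
        assert hits >= 6

    def test_tie_break_prefers_half_when_no_signal(self):
        T = np.ones(40) * 5.0
        scores = pd.Series(np.arange(40, dtype=float))
        rg = threshold_search(scores, T, np.ones(40, bool))
        assert rg.percentile == 0.5

    def test_frozen_cut_applied_to_new_data(self):
        rng = np.random.default_rng(8)
        x, T, E = random_survival(rng, 100, beta=1.0)
        rg = threshold_search(pd.Series(-x), T, E)
        new = pd.Series([rg.score_cut - 1, rg.score_cut + 1])
        assert list(rg.apply(new)) == ["high", "low"]


class TestKendall:
    def test_identical_and_reversed_rankings(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5]})
        assert kendall_cross_modal(t, ("a", "b")) == pytest.approx(1.0)
        t["b"] = t["b"].iloc[::-1].to_numpy()
        assert kendall_cross_modal(t, ("a", "b")) == pytest.approx(-1.0)

    def test_hand_counted_pairs(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [1.0, 3.0, 2.0, 5.0, 4.0]
        # 10 pairs, 8 concordant, 2 discordant -> tau = 0.6
        t = pd.DataFrame({"a": a, "b": b})
        assert kendall_cross_modal(t, ("a", "b")) == pytest.approx(0.6)

    def test_quantiles_within_available_set(self):
        """Missing entries are excluded and do not distort the ranks."""
        t = pd.DataFrame(
            {"a": [1.0, 2, 3, np.nan, 5], "b": [2.0, 4, 6, 1.0, 10]}
        )
        assert kendall_cross_modal(t, ("a", "b")) == pytest.approx(1.0)


class TestCrsAssociation:
    def test_extreme_separation_exact_p(self):
        """Good responders all scoring above poor responders: the most
        extreme of C(6,3)=20 arrangements -> exact one-sided p = 0.05."""
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        crs = pd.Series([1, 1, 1, 3, 3, 3])
        assert crs_association(scores, crs, direction="greater") == pytest.approx(0.05)

    def test_no_shift_not_significant(self):
        scores = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        crs = pd.Series([1, 1, 1, 3, 3, 3])
        assert crs_association(scores, crs) >= 0.5

    def test_direction_flip_enumeration_identity(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        crs = pd.Series([1, 1, 1, 3, 3, 3])
        p_greater = crs_association(scores, crs, direction="greater")
        p_less = crs_association(scores, crs, direction="less")
        # exact enumeration: P(U >= u) + P(U <= u) = 1 + P(U = u)
        assert p_greater + p_less == pytest.approx(1 + 1 / 20)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            crs_association(pd.Series([1.0, 2.0]), pd.Series([1, 1]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40), st.integers(0, 10_000))
def test_permutation_p_bounds(ps, seed):
    """Permutation p always lies in (0, 1] regardless of score structure."""
    rng = np.random.default_rng(seed)
    n = len(ps)
    T = rng.exponential(10, n) + 0.1
    E = np.ones(n, bool)
    p = permutation_test(np.asarray(ps), T, E, n_perm=20, seed=seed)
    assert 0 < p <= 1
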