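"""Signed-rank statistic, permutation tests and repeated-measures ANOVA."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wmdecode import stats


class TestSignedRankStat:
    @pytest.mark.parametrize(
        "diffs,expected",
        [
            ([1.0, 2.0, 3.0], 6.0),
            ([1.0, -2.0, 3.0], 2.0),
            ([-1.0, -2.0, -3.0], -6.0),
            ([1.0, 0.0, -1.0], 0.0),  # zero dropped, tie averaged
        ],
    )
    def test_examples(self, diffs, expected):
        assert stats.signed_rank_stat(diffs) == expected

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            stats.signed_rank_stat([0.0, 0.0])

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=12))
    def test_sign_antisymmetry(self, diffs):
        d = np.asarray(diffs)
        if np.all(d == 0):
            return
        assert stats.signed_rank_stat(-d) == -stats.signed_rank_stat(d)


class TestPermAboveChance:
    def test_strong_signal_gives_p_zero(self):
        real = np.full(6, 0.95)
        rng_null = np.random.default_rng(0)

        def null_fn(rng):
            return 0.5 + rng_null.normal(scale=0.02, size=6)

        out = stats.perm_above_chance(real, null_fn, n_iter=500, seed=1)
        assert out.p_value == 0.0
        assert out.tail == "one_greater"
        assert out.observed_stat > 0

    def test_converges_to_exhaustive_sign_flip_enumeration(self):
        """With all 6 real-null differences positive and magnitudes drawn
        iid symmetric, P(signed-rank <= 0) equals the exhaustive sign-flip
        tail probability; check Monte-Carlo agreement."""
        rng = np.random.default_rng(2)
        magnitudes = rng.uniform(0.02, 0.08, 6)
        real = 0.5 + magnitudes

        def null_fn(rng_):
            # null accuracies symmetric around 0.5 with the same magnitudes
            signs = rng_.choice([-1.0, 1.0], 6)
            return 0.5 + signs * magnitudes

        # exhaustive oracle: over all 2^6 sign patterns of the differences
        # d_i = m_i - s_i * m_i in {0, 2 m_i}: stat <= 0 only when every
        # sign is +1 (all d_i = 0 -> stat treated as 0)
        count = 0
        for signs in itertools.product([-1, 1], repeat=6):
            d = magnitudes - np.array(signs) * magnitudes
            statv = stats.signed_rank_stat(d) if np.any(d != 0) else 0.0
            count += statv <= 0
        exact = count / 64
        assert exact == pytest.approx(1 / 64)

        out = stats.perm_above_chance(real, null_fn, n_iter=2000, seed=3)
        mc_se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(out.p_value - exact) <= 3 * mc_se

    def test_n_iter_validation(self):
        with pytest.raises(ValueError):
            stats.perm_above_chance([0.6], lambda rng: [0.5], n_iter=0)


class TestPermConditionDiff:
    def test_identical_conditions_sentinel(self):
        out = stats.perm_condition_diff([0.6] * 5, [0.6] * 5, n_iter=100, seed=0)
        assert out.p_value == 1.0
        assert out.note == "no difference between conditions"

    def test_clear_difference_small_p(self):
        a = [0.9, 0.88, 0.91, 0.87, 0.92, 0.9]
        b = [0.6, 0.62, 0.58, 0.61, 0.63, 0.6]
        out = stats.perm_condition_diff(a, b, n_iter=1000, seed=0)
        assert out.observed_stat == 21.0  # all positive, n=6
        assert out.p_value < 0.05
        assert out.tail == "two_sided"

    def test_exhaustive_sign_flip_oracle_n6(self):
        """All-positive differences: exact two-sided p over the 64
        equiprobable sign-flip patterns is 2/64; Monte-Carlo must agree."""
        rng = np.random.default_rng(1)
        diffs = rng.uniform(0.05, 0.15, 6)
        obs = stats.signed_rank_stat(diffs)
        n_ge = sum(
            stats.signed_rank_stat(np.array(signs) * diffs) >= obs
            for signs in itertools.product([-1, 1], repeat=6)
        )
        n_le = sum(
            stats.signed_rank_stat(np.array(signs) * diffs) <= obs
            for signs in itertools.product([-1, 1], repeat=6)
        )
        exact = 2 * min(n_ge, n_le) / 64
        assert exact == pytest.approx(2 / 64)
        out = stats.perm_condition_diff(0.5 + diffs, np.full(6, 0.5), n_iter=4000, seed=2)
        mc_se = np.sqrt((1 / 64) * (63 / 64) / 4000)
        assert abs(out.p_value - exact) <= 2 * 3 * mc_se

    def test_argument_order_symmetry(self):
        a = [0.9, 0.7, 0.8, 0.85]
        b = [0.6, 0.65, 0.7, 0.6]
        p1 = stats.perm_condition_diff(a, b, n_iter=2000, seed=5).p_value
        p2 = stats.perm_condition_diff(b, a, n_iter=2000, seed=5).p_value
        assert abs(p1 - p2) < 0.05

    def test_reproducible_under_seed(self):
        a, b = [0.8, 0.7, 0.75, 0.72], [0.6, 0.68, 0.66, 0.7]
        o1 = stats.perm_condition_diff(a, b, n_iter=300, seed=9)
        o2 = stats.perm_condition_diff(a, b, n_iter=300, seed=9)
        assert o1.p_value == o2.p_value
        assert np.array_equal(o1.null_stats, o2.null_stats)


class TestRmAnova:
    def test_f_matches_independent_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        n, a, b = 6, 4, 2
        table = rng.normal(size=(n, a, b))
        F, df = stats.rm_anova_f(table)
        rows = [
            {"subject": i, "roi": j, "condition": k, "y": table[i, j, k]}
            for i in range(n)
            for j in range(a)
            for k in range(b)
        ]
        res = pingouin.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["roi", "condition"],
            subject="subject", detailed=True,
        )
        for key, label in [("roi", "roi"), ("condition", "condition"),
                           ("interaction", "roi * condition")]:
            want = float(res.loc[res.Source == label, "F"].iloc[0])
            assert F[key] == pytest.approx(want, rel=1e-8)
        assert df["roi"] == (a - 1, (a - 1) * (n - 1))
        assert df["interaction"] == ((a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1))

    def test_injected_roi_effect_detected(self):
        rng = np.random.default_rng(1)
        table = rng.normal(scale=0.05, size=(6, 3, 2))
        table[:, 0, :] += 1.0  # strong pure-ROI effect
        out = stats.perm_rm_anova(table, n_iter=500, seed=0)
        assert out.p_roi == 0.0
        assert out.p_condition > 0.05
        assert out.F_roi > out.F_condition

    def test_missing_cells_rejected(self):
        table = np.full((4, 2, 2), np.nan)
        with pytest.raises(ValueError):
            stats.perm_rm_anova(table, n_iter=10)


class TestTimepointTests:
    def test_localized_difference_detected(self):
        rng = np.random.default_rng(0)
        n, T = 6, 12
        v1 = rng.normal(scale=0.05, size=(n, T))
        v2 = rng.normal(scale=0.05, size=(n, T))
        v1[:, 5:8] += 1.0  # difference only at TRs 5-7
        outcomes = stats.timepoint_condition_tests(v1, v2, n_iter=500, seed=1)
        assert len(outcomes) == T
        p = np.array([o.p_value for o in outcomes])
        assert np.all(p[5:8] <= 0.05)
        assert np.mean(p[:5] > 0.05) > 0.6  # mostly non-significant elsewhere

    def test_equal_conditions_sentinel_everywhere(self):
        v = np.ones((4, 5))
        outcomes = stats.timepoint_condition_tests(v, v, n_iter=50, seed=0)
        assert all(o.note == "no difference between conditions" for o in outcomes)


class TestBehavioral:
    def test_identical_columns_give_t0_p1(self):
        acc = np.tile([[90.0, 90.0]], (6, 1))
        rt = np.tile([[0.6, 0.6]], (6, 1))
        res = stats.behavioral_tests(acc, rt)
        assert res["accuracy"]["t"] == 0.0
        assert res["accuracy"]["p"] == 1.0
        assert res["accuracy"]["df"] == 5

    def test_constant_nonzero_diffs_rejected(self):
        acc = np.column_stack([np.full(6, 91.0), np.full(6, 90.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            stats.behavioral_tests(acc, acc)

    def test_t_matches_closed_form(self):
        rng = np.random.default_rng(2)
        a = 90 + rng.normal(size=(6,))
        b = 88 + rng.normal(size=(6,))
        res = stats.behavioral_tests(np.column_stack([a, b]), np.abs(np.column_stack([a, b])) / 100)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        assert res["accuracy"]["t"] == pytest.approx(t_hand, rel=1e-10)


def test_benjamini_hochberg_basic():
    p = np.array([0.001, 0.01, 0.2, 0.8])
    mask = stats.benjamini_hochberg(p, alpha=0.05)
    assert mask.tolist() == [True, True, False, False]


def test_significance_tiers():
    assert [stats.significance_tier(p) for p in (0.0005, 0.005, 0.03, 0.2)] == [3, 2, 1, 0]
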