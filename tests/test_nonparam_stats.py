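"""Tests of the nonparametric kernel against independent oracles.

The Wilcoxon signed-rank exact path is checked against a literal 2^n
enumeration written here (independent of the package's dynamic-programming
tabulation) and against scipy; Kruskal-Wallis against the hand-rank formula
H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 (tie-corrected).
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fingercue.nonparam_stats import (
    effect_size_r,
    fatigue_correlation,
    kruskal_wallis,
    posthoc_pairwise,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(values, alternative):
    """Literal enumeration of all sign assignments of the ranked magnitudes."""
    d = np.asarray(values, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=d.size):
        w = sum(r for r, s in zip(ranks, signs) if s)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
        total += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge / total, le / total))


class TestWilcoxonSignedRank:
    def test_all_positive_six_values_exact(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], alternative="greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 64)

    def test_symmetric_pairs_give_null_result(self):
        res = wilcoxon_signed_rank([-3.0, 3.0, -1.0, 1.0, -2.0, 2.0])
        assert abs(res.z) < 1e-9
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_is_degenerate(self):
        res = wilcoxon_signed_rank([0.0] * 8)
        assert res.p_value == 1.0
        assert "degenerate_all_zero" in res.flags

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_matches_brute_force_enumeration(self, rng, alternative):
        for _ in range(60):
            n = rng.integers(5, 11)
            values = rng.normal(0.4, 1.0, n)
            res = wilcoxon_signed_rank(values, alternative=alternative)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(
                brute_force_wilcoxon_p(values, alternative)
            )

    def test_exact_matches_scipy(self, rng):
        for _ in range(40):
            values = rng.normal(0.5, 1.0, 10)
            ours = wilcoxon_signed_rank(values, alternative="greater")
            theirs = stats.wilcoxon(values, alternative="greater", mode="exact")
            assert ours.p_value == pytest.approx(theirs.pvalue)

    def test_normal_approx_close_to_exact_at_n10(self, rng):
        gaps = []
        for _ in range(1000):
            values = rng.normal(0.3, 1.0, 10)
            p_exact = wilcoxon_signed_rank(values).p_value
            p_approx = wilcoxon_signed_rank(values, exact_cutoff=0).p_value
            gaps.append(abs(p_exact - p_approx))
        assert max(gaps) < 0.03

    def test_z_sign_follows_effect_direction(self):
        up = wilcoxon_signed_rank(np.arange(1.0, 21.0))
        down = wilcoxon_signed_rank(-np.arange(1.0, 21.0))
        assert up.z > 0 > down.z

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False).filter(
                lambda x: abs(x) > 1e-3
            ),
            min_size=5,
            max_size=11,
        ),
        st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_p_invariant_under_positive_rescaling(self, values, scale):
        base = wilcoxon_signed_rank(values)
        scaled = wilcoxon_signed_rank([v * scale for v in values])
        assert base.p_value == pytest.approx(scaled.p_value)

    def test_one_tailed_type_one_error_calibrated(self, rng):
        """Fixed-direction one-tailed test at alpha=0.05 on symmetric null data."""
        rejections = 0
        n_sim = 5000
        for _ in range(n_sim):
            p = wilcoxon_signed_rank(rng.normal(0, 1, 50), alternative="greater").p_value
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


def hand_rank_h(groups):
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    rbar = ranks.mean()
    start, h = 0, 0.0
    for g in groups:
        gr = ranks[start : start + len(g)]
        start += len(g)
        h += len(g) * (gr.mean() - rbar) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(t**3 - t) / (n_total**3 - n_total)
    return h / correction


class TestKruskalWallis:
    def test_identical_groups_give_h_zero(self):
        res = kruskal_wallis([[1.0, 1.0, 1.0]] * 3)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_hand_rank_formula(self, rng):
        for _ in range(100):
            groups = [rng.normal(rng.normal(), 1, rng.integers(3, 9)) for _ in range(3)]
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(hand_rank_h(groups))

    def test_h_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0, 1, 2)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_rejects_tiny_group(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0, 3.0]])


class TestPosthocPairwise:
    def test_identical_groups_all_p_one(self):
        res = posthoc_pairwise([[1, 2, 3, 4]] * 3)
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_outlier_group_has_smallest_p(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(30, 1, 10)]
        res = posthoc_pairwise(groups)
        by_name = {r.name: r.p_value for r in res}
        assert by_name["dunn[0-2]"] < by_name["dunn[0-1]"]
        assert by_name["dunn[1-2]"] < by_name["dunn[0-1]"]

    def test_adjustment_never_decreases_p(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1.5)]
        raw = posthoc_pairwise(groups, method="none")
        holm = posthoc_pairwise(groups, method="holm")
        for r, h in zip(raw, holm):
            assert h.p_value >= r.p_value - 1e-12


class TestEffectSize:
    @pytest.mark.parametrize(
        "z,n,expected",
        [(0.0, 50, 0.0), (6.02, 55, 0.81), (3.47, 55, 0.47), (-6.38, 55, 0.86)],
    )
    def test_r_values(self, z, n, expected):
        assert round(effect_size_r(z, n), 2) == expected

    def test_clipped_and_validated(self):
        assert effect_size_r(100.0, 4) == 1.0
        with pytest.raises(ValueError):
            effect_size_r(1.0, 0)


class TestFatigueCorrelation:
    def _frame(self, reps, values):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": ["S"] * len(reps),
                "experiment": 2,
                "condition": "TUP_IDN",
                "repetition": reps,
                "corrected_error": values,
            }
        )

    def test_perfect_positive_and_negative_correlation(self):
        reps = [1, 2, 3, 4, 5]
        up = fatigue_correlation(self._frame(reps, [float(r) for r in reps]), "TUP_IDN", 2)
        down = fatigue_correlation(
            self._frame(reps, [-float(r) for r in reps]), "TUP_IDN", 2
        )
        assert up.r == pytest.approx(1.0)
        assert down.r == pytest.approx(-1.0)

    def test_constant_errors_flagged(self):
        res = fatigue_correlation(self._frame([1, 2, 3], [2.0, 2.0, 2.0]), "TUP_IDN", 2)
        assert "degenerate_constant_errors" in res.flags

    def test_no_correlation_under_default_generator(self, corrected_errors):
        res = fatigue_correlation(corrected_errors, "TUP_IDN", 2)
        assert abs(res.r) < 0.3
        assert res.p_value > 0.05
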