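"""Effect sizes, two-sample tests, FDR, permutation ANOVA, Wilson interval,
stratification and clock rendering — with enumeration/brute-force oracles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from neuroage.stats import (
    cohens_d,
    deprivation_clock,
    fdr_bh,
    months_days,
    permutation_anova_2x2,
    permutation_ftest,
    stratify_by_percentile,
    two_sample_tests,
    wilson_ci,
)


class TestCohensD:
    def test_hand_computation(self):
        # pooled SD is exactly 1, mean difference -2
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_identical_samples_zero(self):
        x = [1.0, 5.0, 2.5, 7.0]
        assert cohens_d(x, x) == 0.0

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0]
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_constant_unequal_overflow_sentinel(self):
        assert cohens_d([1.0, 1.0], [2.0, 2.0]) == -np.inf
        assert cohens_d([1.0, 1.0], [1.0, 1.0]) == 0.0

    @given(
        st.floats(-10, 10),
        st.floats(0.1, 10),
        st.integers(0, 2**32 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=12)
        b = rng.normal(1, 2, size=15)
        d0 = cohens_d(a, b)
        d1 = cohens_d(scale * a + shift, scale * b + shift)
        assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-9)


class TestTwoSample:
    def test_identical_samples_t(self):
        res = two_sample_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], kind="t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_t_affine_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(0.5, 1, size=12)
        p0 = two_sample_tests(a, b).p
        p1 = two_sample_tests(3 * a + 7, 3 * b + 7).p
        assert p1 == pytest.approx(p0, rel=1e-10)

    def test_mann_whitney_exact_against_enumeration(self):
        x1, x2 = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = two_sample_tests(x1, x2, kind="mann_whitney")
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)
        # oracle: enumerate all C(6,3)=20 assignments of ranks to group 1
        pooled = np.array(x1 + x2)
        obs_u = 0.0
        us = []
        for comb in itertools.combinations(range(6), 3):
            g1 = pooled[list(comb)]
            g2 = pooled[[i for i in range(6) if i not in comb]]
            u = sum((a > b) for a in g1 for b in g2)
            us.append(u)
        us = np.asarray(us, dtype=float)
        # two-sided exact p: as extreme in either direction
        p_oracle = np.mean(np.minimum(us, 9 - us) <= min(obs_u, 9 - obs_u))
        assert res.p == pytest.approx(p_oracle)

    def test_all_tied_mann_whitney(self):
        res = two_sample_tests([2.0, 2.0, 2.0], [2.0, 2.0], kind="mann_whitney")
        assert res.p == 1.0

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        b = rng.normal(0.5, 1, size=30)
        res = two_sample_tests(a, b, kind="mann_whitney")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(float(ref.pvalue))

    def test_welch_option_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.5, 10)
        b = rng.normal(0.3, 3.0, 40)
        p_student = two_sample_tests(a, b).p
        p_welch = two_sample_tests(a, b, welch=True).p
        assert p_student != p_welch


def _fdr_oracle(p):
    """Brute-force BH step-up, written independently of statsmodels."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.037])[0] == pytest.approx(0.037)

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_empty(self):
        assert len(fdr_bh([])) == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(fdr_bh(p), _fdr_oracle(p), atol=1e-12)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(4)
        p = rng.random(20)
        adj = fdr_bh(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestPermutationAnova:
    def test_constant_response_all_p_one(self):
        a = np.repeat([0, 1], 10).astype(bool)
        b = np.tile([0, 1], 10).astype(bool)
        res = permutation_anova_2x2(np.ones(20), a, b, n_perm=199, seed=0)
        assert res.p_a == res.p_b == res.p_ab == 1.0

    def test_pure_main_effect_reaches_minimum_p(self):
        rng = np.random.default_rng(5)
        n_cell = 50
        a = np.repeat([0, 1], 2 * n_cell).astype(bool)
        b = np.tile(np.repeat([0, 1], n_cell), 2).astype(bool)
        y = rng.normal(size=4 * n_cell) + 10.0 * a
        res = permutation_anova_2x2(y, a, b, n_perm=999, seed=1)
        assert res.p_a == pytest.approx(1.0 / 1000.0)
        assert res.p_b > 0.01 and res.p_ab > 0.01

    def test_empty_cell_raises(self):
        a = np.array([0, 0, 1, 1], bool)
        b = np.array([0, 0, 0, 0], bool)
        with pytest.raises(ValueError, match="empty"):
            permutation_anova_2x2(np.arange(4.0), a, b, n_perm=100)

    def test_low_resolution_warns(self):
        a = np.repeat([0, 1], 6).astype(bool)
        b = np.tile([0, 1], 6).astype(bool)
        with pytest.warns(UserWarning, match="permutations"):
            permutation_anova_2x2(np.random.default_rng(0).normal(size=12), a, b, n_perm=50)

    def test_freedman_lane_reduces_to_label_permutation(self):
        """Intercept-only nuisance: FL == exhaustive label permutation."""
        rng = np.random.default_rng(6)
        n = 8
        y = rng.normal(size=n)
        a = np.repeat([1.0, -1.0], 4)
        _, p_fl = permutation_ftest(y, a, None, n_perm="all")
        # oracle: enumerate group assignments, count |t| at least as extreme
        t_obs = sps.ttest_ind(y[:4], y[4:], equal_var=True).statistic ** 2
        stats = []
        for comb in itertools.combinations(range(n), 4):
            g1 = y[list(comb)]
            g2 = y[[i for i in range(n) if i not in comb]]
            stats.append(sps.ttest_ind(g1, g2, equal_var=True).statistic ** 2)
        p_oracle = np.mean(np.asarray(stats) >= t_obs - 1e-12)
        # FL uses the add-one convention over all n! permutations
        assert p_fl == pytest.approx(p_oracle, abs=2.0 / len(stats))

    def test_ter_braak_variant_detects_effects_and_stays_valid(self):
        rng = np.random.default_rng(7)
        a = np.repeat([0, 1], 20).astype(bool)
        b = np.tile(np.repeat([0, 1], 10), 2).astype(bool)
        y = rng.normal(size=40) + 6.0 * a
        res = permutation_anova_2x2(y, a, b, n_perm=999, seed=3, scheme="ter_braak")
        assert res.p_a == pytest.approx(1.0 / 1000.0)
        assert 1.0 / 1000.0 <= res.p_ab <= 1.0

    def test_null_rejection_rates_within_wilson_band(self):
        rng = np.random.default_rng(8)
        a = np.repeat([0, 1], 20).astype(bool)
        b = np.tile(np.repeat([0, 1], 10), 2).astype(bool)
        n_rep = 400
        ps = np.empty(n_rep)
        for i in range(n_rep):
            ps[i] = permutation_anova_2x2(
                rng.standard_normal(40), a, b, n_perm=199, seed=9000 + i
            ).p_ab
        for alpha in (0.05, 0.1):
            lo, hi = wilson_ci(alpha, n_rep)
            assert lo <= np.mean(ps <= alpha) <= hi


class TestWilson:
    def test_boundary_zero(self):
        lo, hi = wilson_ci(0.0, 100)
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert hi > 0

    def test_half_at_n100(self):
        lo, hi = wilson_ci(0.5, 100)
        assert lo == pytest.approx(0.404, abs=0.001)
        assert hi == pytest.approx(0.596, abs=0.001)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = wilson_ci(0.3, 250)
        ref = proportion_confint(int(0.3 * 250), 250, method="wilson")
        assert lo == pytest.approx(ref[0], abs=1e-10)
        assert hi == pytest.approx(ref[1], abs=1e-10)

    def test_validation(self):
        with pytest.raises(ValueError):
            wilson_ci(1.2, 10)
        with pytest.raises(ValueError):
            wilson_ci(0.5, 0)


class TestStratification:
    def test_one_to_ten_hand_quantiles(self):
        labels = stratify_by_percentile(np.arange(1.0, 11.0))
        # 30th/70th percentiles (linear interpolation) are 3.7 and 7.3
        assert set(np.flatnonzero(labels == "low")) == {0, 1, 2}
        assert set(np.flatnonzero(labels == "high")) == {7, 8, 9}
        assert (labels[3:7] == "unassigned").all()

    def test_all_equal_all_unassigned(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = stratify_by_percentile(np.full(12, 3.0))
        assert (labels == "unassigned").all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=50)
        l1 = stratify_by_percentile(scores)
        l2 = stratify_by_percentile(np.exp(scores))
        assert (l1 == l2).all()

    def test_external_reference_population(self):
        scores = np.arange(10.0)
        labels = stratify_by_percentile(scores, reference=np.arange(100.0))
        assert (labels == "low").all()  # all below the reference 30th pct


class TestClock:
    def test_months_days_rendering(self):
        assert months_days(0.4861) == (5, 25)  # 5.833 months
        assert months_days(0.0) == (0, 0)

    def test_identical_strata_zero(self):
        rec = pd.DataFrame({"r_bag": [0.3, 0.3, 0.3, 0.3]})
        labels = np.array(["low", "low", "high", "high"], object)
        clock = deprivation_clock(rec, labels)
        assert clock.diff == 0.0
        assert clock.display == "0 months and 0 days"

    def test_antisymmetry_under_stratum_swap(self):
        rec = pd.DataFrame({"r_bag": [0.1, 0.2, 0.6, 0.9]})
        labels = np.array(["low", "low", "high", "high"], object)
        swapped = np.array(["high", "high", "low", "low"], object)
        assert deprivation_clock(rec, labels).diff == pytest.approx(
            -deprivation_clock(rec, swapped).diff
        )

    def test_empty_stratum_raises(self):
        rec = pd.DataFrame({"r_bag": [0.1, 0.2]})
        with pytest.raises(ValueError):
            deprivation_clock(rec, np.array(["low", "low"], object))
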