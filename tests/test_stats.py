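"""Statistical battery: stepwise regression, ANOVA, Tukey, KS, MAD."""

import numpy as np
import pytest
from scipy import stats as sps

from gravseq.errors import InputError
from gravseq.stats import (adjusted_r2, anova_oneway, ks_two_sample,
                           mad_outliers, stepwise_lm, tukey_hsd)


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2, n, k, expected",
        [(1.0, 100, 3, 1.0), (0.5, 102, 1, 0.495)],
    )
    def test_known_values(self, r2, n, k, expected):
        assert adjusted_r2(r2, n, k) == pytest.approx(expected, abs=1e-12)

    def test_zero_r2_is_nonpositive(self):
        assert adjusted_r2(0.0, 50, 3) <= 0.0

    def test_insufficient_n_rejected(self):
        with pytest.raises(InputError):
            adjusted_r2(0.5, 4, 3)


class TestStepwise:
    def test_single_true_predictor_recovered(self):
        r = np.random.default_rng(7)
        x1 = r.normal(size=200)
        x2 = r.normal(size=200)
        y = 2.0 * x1 + r.normal(0, 0.1, 200)
        res = stepwise_lm(y, {"x1": x1, "x2": x2})
        assert res.terms == ["x1"]
        assert 1.9 <= res.coefficients["x1"] <= 2.1
        assert res.adj_r2 > 0.99

    def test_pure_interaction_enters_with_hierarchy(self):
        r = np.random.default_rng(11)
        x1 = r.normal(size=500)
        x2 = r.normal(size=500)
        y = 1.5 * x1 * x2 + r.normal(0, 0.2, 500)
        res = stepwise_lm(y, {"x1": x1, "x2": x2})
        assert "x1:x2" in res.terms
        assert {"x1", "x2"}.issubset(res.terms)  # parents kept by hierarchy

    def test_null_entry_rate_matches_p_enter(self):
        """Under a global null, each candidate enters at ~p_enter, so the
        chance of an intercept-only model is ~(1-p_enter)^3."""
        hits = 0
        n_runs = 200
        for s in range(n_runs):
            r = np.random.default_rng(1000 + s)
            y = r.normal(size=500)
            cand = {f"x{i}": r.normal(size=500) for i in range(3)}
            res = stepwise_lm(y, cand)
            hits += bool(res.terms)
        expected = 1 - 0.95**3  # ~0.143
        se = np.sqrt(expected * (1 - expected) / n_runs)
        assert abs(hits / n_runs - expected) < 4 * se

    def test_listwise_nan_handling(self):
        r = np.random.default_rng(3)
        x = r.normal(size=300)
        y = 3 * x + r.normal(0, 0.1, 300)
        y[::10] = np.nan
        x_nan = x.copy()
        x_nan[1::10] = np.nan
        res = stepwise_lm(y, {"x": x_nan})
        assert res.terms == ["x"]
        assert res.n_obs == 300 - 30 - 30

    def test_constant_candidate_rejected(self):
        with pytest.raises(InputError, match="constant"):
            stepwise_lm(np.random.default_rng(0).normal(size=50),
                        {"c": np.ones(50)})

    def test_final_p_values_match_ols(self):
        """Dual route: the final model's t-test p-values agree with an
        independent OLS fit of the same design."""
        sm = pytest.importorskip("statsmodels.api")
        r = np.random.default_rng(5)
        x1 = r.normal(size=150)
        x2 = r.normal(size=150)
        y = 1.2 * x1 - 0.8 * x2 + r.normal(0, 0.5, 150)
        res = stepwise_lm(y, {"x1": x1, "x2": x2})
        assert set(res.terms) == {"x1", "x2"}
        X = sm.add_constant(np.column_stack([x1, x2]))
        fit = sm.OLS(y, X).fit()
        assert res.coefficients["x1"] == pytest.approx(fit.params[1], rel=1e-8)
        assert res.p_values["x1"] == pytest.approx(fit.pvalues[1], rel=1e-6)
        assert res.adj_r2 == pytest.approx(fit.rsquared_adj, rel=1e-10)


class TestAnova:
    def test_degenerate_separation(self):
        res = anova_oneway({"a": np.zeros(3), "b": np.ones(3)})
        assert res.f == np.inf and res.p_value == 0.0

    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        res = anova_oneway({"a": x, "b": x.copy()})
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_sums_of_squares(self):
        groups = {
            "g1": np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
            "g2": np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
            "g3": np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0]),
        }
        # independent oracle: brute-force decomposition
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_oracle = (ssb / 2) / (ssw / 15)
        res = anova_oneway(groups)
        assert res.f == pytest.approx(f_oracle, rel=1e-12)
        scipy_res = sps.f_oneway(*groups.values())
        assert res.f == pytest.approx(scipy_res.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(scipy_res.pvalue, rel=1e-10)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        res = anova_oneway({"a": a, "b": b})
        t = sps.ttest_ind(a, b).statistic
        assert res.f == pytest.approx(t**2, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            anova_oneway({"only": np.arange(5.0)})


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        x = np.arange(10.0)
        res = tukey_hsd({"a": x, "b": x + 0.001, "c": x - 0.001})
        assert not res.comparisons["significant"].any()

    def test_two_groups_matches_pooled_t(self, rng):
        """For k=2 the studentized range is sqrt(2)|t|, so the Tukey p
        equals the pooled two-sample t-test p."""
        a, b = rng.normal(0, 1, 40), rng.normal(0.6, 1, 28)
        res = tukey_hsd({"a": a, "b": b})
        p_t = sps.ttest_ind(a, b).pvalue
        assert res.comparisons.loc[0, "p_adj"] == pytest.approx(p_t, abs=1e-6)

    def test_shifted_group_detected_exactly(self, rng):
        groups = {f"g{i}": rng.normal(0, 1, 50) for i in range(3)}
        groups["shifted"] = rng.normal(5, 1, 50)
        res = tukey_hsd(groups)
        sig = res.comparisons[res.comparisons["significant"]]
        assert len(sig) == 3
        assert all("shifted" in (r.group_a, r.group_b)
                   for r in sig.itertuples())

    def test_all_pairs_present_once(self, rng):
        res = tukey_hsd({k: rng.normal(size=10) for k in "abcd"})
        pairs = {frozenset((r.group_a, r.group_b))
                 for r in res.comparisons.itertuples()}
        assert len(pairs) == len(res.comparisons) == 6

    def test_adjusted_p_conservative(self, rng):
        """Tukey p is never below the unadjusted pairwise t-test p."""
        groups = {k: rng.normal(loc, 1, 30)
                  for k, loc in zip("abcd", [0, 0.2, 0.5, 0.9])}
        res = tukey_hsd(groups)
        for r in res.comparisons.itertuples():
            p_raw = sps.ttest_ind(groups[r.group_a], groups[r.group_b]).pvalue
            assert r.p_adj >= p_raw - 1e-9

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        groups = {k: rng.normal(loc, 1, n)
                  for k, loc, n in zip("abc", [0, 0.4, 0.8], [20, 35, 27])}
        res = tukey_hsd(groups)
        data = np.concatenate(list(groups.values()))
        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        ref = sm.pairwise_tukeyhsd(data, labels)
        np.testing.assert_allclose(
            res.comparisons["p_adj"].to_numpy(), ref.pvalues, atol=1e-6
        )


class TestKS:
    def test_self_comparison_zero(self, rng):
        x = rng.normal(size=100)
        res = ks_two_sample(x, x.copy())
        assert res.d == 0.0

    def test_disjoint_supports(self):
        res = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert res.d == 1.0

    def test_enumerated_ecdf(self):
        # ECDFs of {1,2} and {1,3} differ by at most 1/2 (at x in [2,3))
        res = ks_two_sample([1, 2], [1, 3])
        assert res.d == pytest.approx(0.5)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=200), rng.normal(0.3, 1, 150)
        assert ks_two_sample(x, y).d == ks_two_sample(y, x).d

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            ks_two_sample([], [1.0])


class TestMadOutliers:
    def test_single_extreme_flagged(self):
        flags = mad_outliers([1.0, 1.0, 1.1, 0.9, 100.0])
        assert flags.tolist() == [False, False, False, False, True]

    def test_all_equal_none_flagged(self):
        assert not mad_outliers(np.ones(10)).any()

    def test_zero_mad_flags_exact_deviants(self):
        flags = mad_outliers([1.0, 1.0, 1.0, 1.0, 2.0])
        assert flags.tolist() == [False] * 4 + [True]

    def test_normal_false_positive_rate(self, rng):
        """k=3 on scaled MAD flags well under 1% of standard normals."""
        flags = mad_outliers(rng.standard_normal(1000), k=3)
        assert flags.mean() < 0.01

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError):
            mad_outliers([1.0, 2.0])
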