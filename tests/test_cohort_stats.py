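import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dcekin import (bland_altman, classify_risk, fdr_adjust, icc_two_reader,
                    mann_whitney_u, mcnemar, median_ci, roc_analysis, spearman,
                    wilcoxon_signed_rank)
from dcekin.cohort_stats import apply_exclusions, run_group_comparison
from dcekin.synthetic import generate_screening_roster


class TestClassifyRisk:
    def test_low_risk_rule(self):
        assert classify_risk("endometrioid", 1, False, False, False, False) == "low"
        assert classify_risk("endometrioid", 2, False, False, False, False) == "low"

    def test_high_risk_variants(self):
        assert classify_risk("nonendometrioid", None, False, False, False, False) == "high"
        assert classify_risk("endometrioid", 3, False, False, False, False) == "high"
        assert classify_risk("endometrioid", 2, True, False, False, False) == "high"
        assert classify_risk("endometrioid", 1, False, False, False, True) == "high"

    def test_endometrioid_requires_grade(self):
        with pytest.raises(ValueError, match="grade"):
            classify_risk("endometrioid", None, False, False, False, False)


def _brute_force_mw_p(x, y):
    """Exact two-sided p by enumerating all group-label arrangements."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    obs = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    m = len(pooled) - nx
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        xx = pooled[list(idx)]
        yy = np.delete(pooled, list(idx))
        u = sps.mannwhitneyu(xx, yy, alternative="two-sided").statistic
        # two-sided: as-or-more-extreme U on either tail
        dev = abs(u - nx * m / 2.0)
        if dev >= abs(obs - nx * m / 2.0) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(0.100, abs=1e-9)

    def test_identical_samples_degenerate(self):
        res = mann_whitney_u([1, 1], [1, 1])
        assert res.p_raw == 1.0 and res.degenerate

    def test_symmetric_multisets(self):
        assert mann_whitney_u([1, 2], [1, 2]).p_raw == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(1.0, 8.0))[:4]
        y = np.setdiff1d(np.arange(1.0, 8.0), x)[:3]
        res = mann_whitney_u(x, y)
        assert res.p_raw == pytest.approx(_brute_force_mw_p(x, y), abs=1e-9)

    def test_auc_identity_with_rank_sum(self, rng):
        # ROC AUC of pooled scores equals U_y/(n_x n_y) for tie-free data
        x = rng.normal(0, 1, 15)
        y = rng.normal(1, 1, 12)
        u_y = sps.mannwhitneyu(y, x, alternative="two-sided").statistic
        roc = roc_analysis(np.concatenate([x, y]),
                           np.array(["low"] * 15 + ["high"] * 12))
        assert roc.auc == pytest.approx(u_y / (15 * 12), abs=1e-12)


def _brute_force_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return np.minimum(adj, 1.0)


class TestFDR:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_largest_raw_p_within_family_unchanged(self):
        # model-family structure: the largest raw p keeps its raw value
        p = [1e-4, 1e-4, 0.39, 1e-4, 1e-4, 0.08, 1e-4, 0.61, 1e-4, 0.52]
        fam = ["et"] * 4 + ["dp"] * 6
        adj = fdr_adjust(p, fam)
        assert adj[2] == pytest.approx(0.39)
        assert adj[7] == pytest.approx(0.61)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(9)
        np.testing.assert_allclose(fdr_adjust(p), _brute_force_bh(p), atol=1e-12)

    def test_monotone_never_below_raw_idempotent(self, rng):
        p = rng.random(12)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        np.testing.assert_allclose(fdr_adjust(adj), fdr_adjust(adj))


class TestWilcoxon:
    def test_all_positive_exact(self):
        # all 5 signs positive: 2/32 sign assignments as extreme
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5]).p_raw == pytest.approx(0.0625)

    def test_symmetric_differences(self):
        assert wilcoxon_signed_rank([-2, -1, 1, 2]).p_raw == pytest.approx(1.0)

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([0, 0, 0])
        assert res.p_raw == 1.0 and res.degenerate

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.permutation([1.5, -2.5, 3.5, 4.5, -5.5, 6.5])
        res = wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([1, -1], repeat=len(d)):
            w = ranks[np.array(signs) > 0].sum()
            w = min(w, ranks.sum() - w)
            if w <= obs + 1e-9:
                count += 1
        assert res.p_raw == pytest.approx(count / 2 ** len(d), abs=1e-9)


class TestBlandAltman:
    def test_identical_methods(self):
        res = bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0
        assert res.trend_rho is None

    def test_hand_computed_limits(self):
        res = bland_altman([1.1, 2.2, 3.3], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(0.2)
        assert res.sd_diff == pytest.approx(0.1)
        assert res.loa_low == pytest.approx(0.004)
        assert res.loa_high == pytest.approx(0.396)

    def test_constant_offset_has_no_trend(self, rng):
        x = rng.integers(1, 100, 20) / 4.0       # exactly representable
        res = bland_altman(x + 0.5, x)
        # constant difference: no trend (undefined under total ties)
        assert res.trend_rho is None or res.trend_rho == pytest.approx(0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_constant_input_flagged(self):
        rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)

    def test_matches_rank_formula_on_tie_free_data(self, rng):
        for _ in range(50):
            x = rng.permutation(10).astype(float)
            y = rng.permutation(10).astype(float)
            rho, _ = spearman(x, y)
            d = sps.rankdata(x) - sps.rankdata(y)
            n = len(x)
            assert rho == pytest.approx(1 - 6 * (d**2).sum() / (n * (n**2 - 1)), abs=1e-12)

    def test_exact_small_n_p_value(self):
        # n=4 monotone: 2 of 24 permutations reach |rho| = 1
        _, p = spearman([1, 2, 3, 4], [2, 4, 6, 8])
        assert p == pytest.approx(2 / 24)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([1, 2, 3, 10, 11, 12],
                           ["low"] * 3 + ["high"] * 3)
        assert roc.auc == 1.0
        assert roc.sensitivity == 100.0 and roc.specificity == 100.0

    def test_uninformative_values(self):
        roc = roc_analysis([5.0] * 6, ["low"] * 3 + ["high"] * 3)
        assert roc.auc == pytest.approx(0.5)

    def test_orientation_flips_for_lower_positive(self, rng):
        # positive (high-risk) class has LOWER values: orientation "<="
        low = rng.normal(10, 1, 20)
        high = rng.normal(6, 1, 20)
        roc = roc_analysis(np.r_[low, high], np.array(["low"] * 20 + ["high"] * 20))
        assert roc.orientation == "<="
        assert roc.auc > 0.9

    def test_confusion_matrix_consistency(self, rng):
        values = np.r_[rng.normal(0, 1, 15), rng.normal(1.2, 1, 17)]
        labels = np.array(["low"] * 15 + ["high"] * 17)
        roc = roc_analysis(values, labels)
        pred = (values >= roc.cutoff) if roc.orientation == ">=" else (values <= roc.cutoff)
        y = labels == "high"
        sens = 100.0 * np.sum(pred & y) / y.sum()
        spec = 100.0 * np.sum(~pred & ~y) / (~y).sum()
        acc = 100.0 * np.mean(pred == y)
        assert roc.sensitivity == pytest.approx(sens)
        assert roc.specificity == pytest.approx(spec)
        assert roc.accuracy == pytest.approx(acc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], ["low", "low", "low"])


class TestMcNemar:
    def test_exact_binomial(self):
        # b=1, c=8 discordant pairs: p = 2 sum_{k<=1} C(9,k)/2^9 = 20/512
        a = np.array([True] * 1 + [False] * 8 + [True] * 5)
        b = np.array([False] * 1 + [True] * 8 + [True] * 5)
        assert mcnemar(a, b).p_raw == pytest.approx(20 / 512)

    def test_symmetric_discordance(self):
        a = np.array([True] * 3 + [False] * 3)
        b = np.array([False] * 3 + [True] * 3)
        assert mcnemar(a, b).p_raw == pytest.approx(1.0)

    def test_no_discordance_degenerate(self):
        a = np.array([True, False, True])
        res = mcnemar(a, a)
        assert res.p_raw == 1.0 and res.degenerate


class TestICC:
    def test_perfect_agreement(self):
        res = icc_two_reader([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_category_thresholds(self):
        assert 0.40 <= 0.715 <= 0.75     # good band
        assert 0.952 > 0.75              # excellent band
        r = icc_two_reader([1, 2, 3, 4.0], [1.2, 1.9, 3.3, 3.8])
        assert r.category in ("good", "excellent")

    def test_hand_computed_mean_squares(self):
        # worked 4x2 table; ICC(2,1) from the ANOVA decomposition
        r1 = np.array([9.0, 6.0, 8.0, 7.0])
        r2 = np.array([2.0, 1.0, 4.0, 1.0])
        data = np.column_stack([r1, r2])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((data - data.mean(1, keepdims=True) - data.mean(0)
                 + grand) ** 2).sum()) / ((n - 1) * (k - 1))
        expect = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_two_reader(r1, r2).icc == pytest.approx(expect, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        r1 = rng.normal(10, 2, 12)
        r2 = r1 + rng.normal(0, 1, 12) + 0.5
        df = pd.DataFrame({
            "targets": np.tile(np.arange(12), 2),
            "raters": np.repeat(["a", "b"], 12),
            "scores": np.r_[r1, r2],
        })
        icc2 = pg.intraclass_corr(df, targets="targets", raters="raters",
                                  ratings="scores").set_index("Type").loc["ICC(A,1)", "ICC"]
        assert icc_two_reader(r1, r2).icc == pytest.approx(icc2, abs=1e-9)

    def test_zero_variance_flagged(self):
        res = icc_two_reader([1.0, 1, 1], [1.0, 1, 1])
        assert np.isnan(res.icc)


class TestMedianCI:
    def test_coverage_at_n_25(self):
        # binomial order-statistic interval covers the true median >= 93%
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(1000):
            x = rng.lognormal(0.0, 0.5, 25)
            _, lo, hi = median_ci(x)
            if lo <= 1.0 <= hi:     # true median of lognormal(0, s) is 1
                hits += 1
        assert hits / 1000 >= 0.93


class TestExclusionAccounting:
    def test_default_roster_leaves_51(self):
        roster = generate_screening_roster(seed=7)
        included, counts = apply_exclusions(roster)
        assert len(roster) == 112
        assert len(included) == 51
        assert sum(counts.values()) == 61
        assert sorted(counts.values(), reverse=True) == [33, 9, 7, 6, 6]


def _medians_cohort(n_low=12, n_high=13, seed=5, shift=True):
    rng = np.random.default_rng(seed)
    from dcekin.synthetic import GROUP_MEDIANS
    rows = []
    for i, grp in enumerate(["low"] * n_low + ["high"] * n_high):
        med = GROUP_MEDIANS[grp]
        f = np.exp(rng.normal(0, 0.25, 8))
        rows.append({
            "id": f"p{i}", "risk": grp,
            "et_Ktrans": med["Ktrans"] * f[0], "et_Vp": med["Vp_et"] * f[1],
            "et_Ve": med["Ve"] * f[2], "et_Kep": 100 * med["Ktrans"] / med["Ve"] * f[3],
            "dp_F": med["F"] * f[4], "dp_MTT": med["MTT"] * f[5],
            "dp_Vp": med["Vp_dp"] * f[6], "dp_Ve": med["Ve"] * f[2] * 0.95,
            "dp_PS": med["PS"] * f[7],
            "dp_E": 100 * (1 - np.exp(-med["PS"] / med["F"])) * f[7] ** 0.3,
            "mvd": (55.0 if grp == "low" else 90.0) * f[1] ** 0.5,
        })
    return pd.DataFrame(rows)


class TestRunGroupComparison:
    def test_direction_of_significant_differences(self):
        report = run_group_comparison(_medians_cohort())
        gc = report["group_comparison"]
        for p in ("et_Ktrans", "et_Kep", "et_Vp", "dp_F", "dp_Vp", "dp_PS"):
            assert gc[p]["direction"] == "lower_in_high", p
        assert gc["et_Ve"]["p_adjusted"] > 0.05
        assert "Ve" in report["agreement"] and "Vp" in report["agreement"]
        assert report["roc"]["mvd"]["auc"] > 0.5

    def test_identical_patients_uninformative(self):
        df = _medians_cohort()
        cols = [c for c in df.columns if c not in ("id", "risk")]
        df[cols] = 1.0
        report = run_group_comparison(df)
        for r in report["group_comparison"].values():
            assert r["p_raw"] == 1.0
        for r in report["roc"].values():
            assert r["auc"] == pytest.approx(0.5)

    def test_single_model_cohort_omits_dp(self):
        df = _medians_cohort()[["id", "risk", "et_Ktrans", "et_Vp", "et_Ve", "et_Kep"]]
        report = run_group_comparison(df)
        assert all(k.startswith("et_") for k in report["group_comparison"])
        assert report["agreement"] == {}
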