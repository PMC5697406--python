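"""Regression battery, age-group summaries and shared test utilities."""

import numpy as np
import pandas as pd
import pytest

from mtqq.association import (
    age_models,
    bonferroni_alpha,
    chi_square_prop,
    fit_linear,
    group_summary,
    haplogroup_scan,
    homoplasmy_scan,
    phenotype_scan,
    welch_t,
)
from mtqq.calling import HeteroplasmyCall


def het(sample, maf, pos=10):
    return HeteroplasmyCall(sample, pos, "A", "G", maf, 500, 10, 10)


class TestFitLinear:
    def test_exact_fit_has_zero_se(self):
        x = np.arange(10.0)
        res = fit_linear(2 * x, {"x": x})
        assert res["x"]["estimate"] == pytest.approx(2.0)
        assert res["x"]["se"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n,p", [(30, 2), (80, 5)])
    def test_matches_normal_equation_oracle(self, n, p):
        rng = np.random.default_rng(n + p)
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        res = fit_linear(y, pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]))
        Xd = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert res.params == pytest.approx(beta, abs=1e-10)

    def test_underdetermined_errors(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, 2.0], {"a": [1, 2], "b": [3, 4]})

    def test_collinear_design_names_term(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError, match="x2"):
            fit_linear(np.ones(30), {"x1": x, "x2": 2 * x})


class TestUtilities:
    @pytest.mark.parametrize(
        "m,expected,tol",
        [(1, 0.05, 0), (186, 2.69e-4, 5e-7), (32, 0.0016, 5e-5)],
    )
    def test_bonferroni_thresholds(self, m, expected, tol):
        assert bonferroni_alpha(m) == pytest.approx(expected, abs=tol or 1e-15)

    def test_bonferroni_requires_tests(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)

    def test_welch_matches_scipy_and_df(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 2, 25)
        t, df, p = welch_t(a, b)
        from scipy import stats

        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        assert df == pytest.approx(ref.df)

    def test_chi_square_prop_hand_value(self):
        # 2x2 [[30,70],[10,90]] without continuity correction: chi2 = 12.5
        stat, p = chi_square_prop(30, 100, 10, 100)
        assert stat == pytest.approx(12.5)
        assert 0 < p < 0.001


@pytest.fixture(scope="module")
def synthetic_frame():
    rng = np.random.default_rng(11)
    n = 1500
    age = rng.uniform(18, 85, n)
    hets = rng.poisson(0.3 + 0.011 * age)
    cn = 130 - 0.395 * age + rng.gamma(1.664, 58.8, n)
    wbc = rng.normal(7, 2, n)
    plat = rng.normal(250, 60, n)
    nuc = rng.normal(5.5, 0.4, n)
    phen = pd.DataFrame({"age": age, "wbc": wbc, "platelets": plat})
    return hets, cn, phen, nuc


class TestAgeModels:
    def test_slopes_recovered_within_three_se(self, synthetic_frame):
        hets, cn, phen, nuc = synthetic_frame
        models = age_models(hets, cn, phen, nuc)
        h = models["het_vs_age"]["age"]
        assert abs(h["estimate"] - 0.011) < 3 * h["se"]
        c = models["cn_vs_age"]["age"]
        assert abs(c["estimate"] - (-0.395)) < 3 * c["se"]

    def test_joint_model_finds_both_terms(self, synthetic_frame):
        hets, cn, phen, nuc = synthetic_frame
        models = age_models(hets, cn, phen, nuc)
        joint = models["age_joint"]
        assert joint["het_count"]["p"] < 0.05
        assert joint["copy_number"]["p"] < 0.05
        blood = models["age_joint_blood"]
        assert set(blood.terms) >= {"het_count", "copy_number", "wbc", "platelets"}
        assert "cn_vs_het" in models


class TestGroupSummary:
    def test_stratum_means_sum_to_total(self):
        rng = np.random.default_rng(4)
        ages = pd.Series(rng.uniform(20, 84, 200), index=[f"s{i}" for i in range(200)])
        calls = {}
        for s in ages.index:
            k = rng.poisson(1.2)
            calls[s] = [het(s, float(m)) for m in rng.uniform(0.02, 0.5, k)]
        out = group_summary(calls, ages)
        filled = out.dropna(subset=["het_mean_total"])
        assert np.allclose(
            filled.het_mean_total, filled.het_mean_maf_2_5 + filled.het_mean_maf_gt5
        )
        for col in ("carrier_prop_total", "carrier_prop_maf_2_5", "carrier_prop_maf_gt5"):
            assert filled[col].between(0, 1).all()

    def test_boundary_maf_005_belongs_to_low_stratum(self):
        ages = pd.Series([45.0], index=["s1"])
        out = group_summary({"s1": [het("s1", 0.05)]}, ages)
        row = out.set_index("age_group").loc["40-50"]
        assert row.het_mean_maf_2_5 == 1.0
        assert row.het_mean_maf_gt5 == 0.0

    def test_age_bins_left_closed(self):
        ages = pd.Series([40.0, 39.999], index=["a", "b"])
        out = group_summary({"a": [], "b": []}, ages).set_index("age_group")
        assert out.loc["40-50", "n"] == 1
        assert out.loc["<40", "n"] == 1


class TestScans:
    def test_phenotype_couplings_recovered(self):
        rng = np.random.default_rng(21)
        n = 1500
        age = rng.uniform(18, 85, n)
        cn = 130 - 0.395 * age + rng.gamma(1.664, 58.8, n)
        z = (cn - cn.mean()) / cn.std()
        phen = pd.DataFrame(
            {
                "bicarbonate": 26 + 2.65 * (0.102 * z + np.sqrt(1 - 0.102**2) * rng.normal(size=n)),
                "wbc": 7 + 2 * (-0.116 * z + np.sqrt(1 - 0.116**2) * rng.normal(size=n)),
                "null1": rng.normal(size=n),
            }
        )
        out = phenotype_scan(cn, phen, age).set_index("trait")
        for trait, eff in (("bicarbonate", 0.102), ("wbc", -0.116)):
            se_eff = out.loc[trait, "se"] * np.std(cn, ddof=1) / phen[trait].std(ddof=1)
            assert abs(out.loc[trait, "effect_per_sd"] - eff) < 3 * se_eff

    def test_constant_trait_skipped(self):
        phen = pd.DataFrame({"flat": np.ones(50), "ok": np.arange(50.0)})
        with pytest.warns(UserWarning, match="constant"):
            out = phenotype_scan(np.random.default_rng(0).normal(size=50), phen, np.arange(50.0))
        assert list(out.trait) == ["ok"]

    def test_homoplasmy_scan_carrier_threshold_strict(self):
        rng = np.random.default_rng(2)
        n = 300
        geno = pd.DataFrame(
            {
                "at_1pct": np.r_[np.ones(3), np.zeros(n - 3)],  # exactly 1%
                "above": np.r_[np.ones(30), np.zeros(n - 30)],
            }
        )
        out = homoplasmy_scan(
            rng.normal(200, 40, n), geno, rng.uniform(20, 80, n), rng.normal(5.5, 0.4, n)
        )
        assert list(out.variant) == ["above"]

    def test_homoplasmy_scan_detects_planted_shift(self):
        rng = np.random.default_rng(3)
        n = 1500
        carrier = (rng.uniform(size=n) < 0.05).astype(float)
        cn = rng.normal(200, 40, n) + 40 * carrier  # 1 SD shift
        geno = pd.DataFrame({"v": carrier})
        out = homoplasmy_scan(cn, geno, rng.uniform(20, 80, n), rng.normal(5.5, 0.4, n))
        assert out.iloc[0].significant

    def test_haplogroup_scan_planted_effect_and_errors(self):
        rng = np.random.default_rng(4)
        n = 400
        labels = rng.choice(["H", "U", "K"], size=n, p=[0.6, 0.3, 0.1])
        feature = rng.normal(200, 30, n) + 20 * (labels == "U")
        out = haplogroup_scan(feature, labels).set_index("haplogroup")
        assert out.loc["U", "p"] < 0.01
        with pytest.raises(ValueError):
            haplogroup_scan(feature, ["H"] * n)

    def test_haplogroup_singletons_pooled(self):
        labels = ["H"] * 20 + ["U"] * 20 + ["Z"]
        feature = np.random.default_rng(5).normal(size=41)
        out = haplogroup_scan(feature, labels)
        assert set(out.haplogroup) == {"H", "U", "other"}
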