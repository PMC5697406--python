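"""Kernel association test: matrix construction, null math, oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtqq.calling import AlleleCountTable
from mtqq.kernel import (
    HetGenotypeMatrix,
    KernelAssociationModel,
    KernelTestBattery,
    build_het_matrix,
    pc_covariates,
    skat,
    skat_permutation,
)
from conftest import make_counts

A, C, G, T = 0, 1, 2, 3


class TestBuildMatrix:
    def _table(self, minor_count, depth=300):
        fills = [
            (10, A, 0, (depth - minor_count) // 2),
            (10, A, 1, depth - minor_count - (depth - minor_count) // 2),
            (10, G, 0, minor_count // 2),
            (10, G, 1, minor_count - minor_count // 2),
        ]
        return AlleleCountTable("s", make_counts(100, fills))

    def test_minor_count_five_is_zero_six_is_fraction(self):
        X5 = build_het_matrix([self._table(5)], [(10, "G")])
        assert X5.values[0, 0] == 0.0
        X6 = build_het_matrix([self._table(6)], [(10, "G")])
        assert X6.values[0, 0] == pytest.approx(6 / 300)

    def test_binary_mode_indicator(self):
        X = build_het_matrix([self._table(6)], [(10, "G")], mode="binary")
        assert X.values[0, 0] == 1.0

    def test_cell_uses_samples_own_minor_allele(self):
        """At a population-polymorphic site a non-carrier homoplasmic for the
        named allele must read 0, not its major-allele fraction."""
        fills = [(10, G, 0, 150), (10, G, 1, 150)]  # G-homoplasmic sample
        t = AlleleCountTable("s", make_counts(100, fills))
        X = build_het_matrix([t], [(10, "G")])
        assert X.values[0, 0] == 0.0

    def test_exclude_polymorphic_drops_sites(self):
        X = build_het_matrix(
            [self._table(20)], [(10, "G"), (20, "C")], exclude_polymorphic={(10, "G")}
        )
        assert X.sites == [(20, "C")]

    def test_mode_invariants(self):
        with pytest.raises(ValueError):
            HetGenotypeMatrix(np.array([[0.7]]), ["s"], [(1, "G")], mode="maf")
        with pytest.raises(ValueError):
            HetGenotypeMatrix(np.array([[0.5]]), ["s"], [(1, "G")], mode="binary")


class TestPcCovariates:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        G = np.zeros((40, 30))
        G[:20, :15] = 1
        G[20:, 15:] = 1
        G = np.abs(G - (rng.uniform(size=G.shape) < 0.05))
        pcs = pc_covariates(G, k=2)
        side = pcs[:, 0] > np.median(pcs[:, 0])
        assert side[:20].all() != side[20:].all()
        assert abs(side[:20].mean() - side[20:].mean()) > 0.9

    def test_orthogonality(self):
        rng = np.random.default_rng(1)
        pcs = pc_covariates(rng.integers(0, 2, size=(50, 40)), k=3)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_identical_rows_error(self):
        with pytest.raises(ValueError):
            pc_covariates(np.ones((10, 5)), k=2)


def _dataset(n=200, m=15, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, m))
    carriers = rng.integers(0, n, size=m)
    X[carriers, np.arange(m)] = rng.uniform(0.02, 0.4, size=m)
    C = np.column_stack([rng.uniform(20, 80, n), rng.normal(200, 50, n)])
    w = rng.uniform(5, 20, m)
    y = 0.3 * C[:, 0] / 50 + effect * (X * w).sum(1) + rng.normal(size=n)
    return y, C, X, w


class TestSkat:
    def test_zero_matrix_degenerate(self):
        y, C, X, w = _dataset()
        res = skat(y, C, np.zeros_like(X), w)
        assert (res.q, res.p) == (0.0, 1.0)
        assert res.degenerate

    def test_m1_reduces_to_single_regressor_score_test(self):
        rng = np.random.default_rng(42)
        n = 500
        x = rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        y = 0.1 * x + rng.normal(size=n)
        res = skat(y, C, x[:, None], np.array([2.0]))
        ols = pd.DataFrame({"x": x, "c1": C[:, 0], "c2": C[:, 1]})
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(ols)).fit()
        assert res.p == pytest.approx(fit.pvalues["x"], abs=0.01)

    def test_invariant_under_covariate_reparameterization(self):
        y, C, X, w = _dataset(seed=3)
        res1 = skat(y, C, X, w)
        rng = np.random.default_rng(4)
        M = rng.normal(size=(2, 2))
        while abs(np.linalg.det(M)) < 0.1:
            M = rng.normal(size=(2, 2))
        res2 = skat(y, C @ M + np.array([3.0, -7.0]), X, w)
        assert res2.q == pytest.approx(res1.q, rel=1e-8)
        assert res2.p == pytest.approx(res1.p, rel=1e-6)

    def test_doubling_weights_quadruples_q_keeps_p(self):
        y, C, X, w = _dataset(seed=5)
        res1 = skat(y, C, X, w)
        res2 = skat(y, C, X, 2 * w)
        assert res2.q == pytest.approx(4 * res1.q, rel=1e-10)
        assert res2.p == pytest.approx(res1.p, rel=1e-8)

    def test_binary_equals_maf_when_entries_are_one(self):
        y, C, X, w = _dataset(seed=6)
        Xb = (X > 0).astype(float)
        res_maf = skat(y, C, Xb, w)
        Xm = HetGenotypeMatrix(Xb, [str(i) for i in range(len(y))],
                               [(i + 1, "G") for i in range(X.shape[1])], mode="binary")
        res_bin = skat(y, C, Xm, w)
        assert res_bin.q == pytest.approx(res_maf.q)
        assert res_bin.p == pytest.approx(res_maf.p)

    def test_missing_weights_filled_with_median(self):
        y, C, X, w = _dataset(seed=7)
        w = w.copy()
        w[0] = np.nan
        with pytest.warns(UserWarning, match="median"):
            res = skat(y, C, X, w)
        w[0] = np.median(w[1:])
        assert res.q == pytest.approx(skat(y, C, X, w).q)

    def test_log_transform_requires_positive(self):
        y, C, X, w = _dataset(seed=8)
        with pytest.raises(ValueError, match="positive"):
            skat(y - y.max() - 1, C, X, w, log_transform=True)

    def test_battery_matches_per_trait_skat(self):
        y, C, X, w = _dataset(seed=9)
        battery = KernelTestBattery(X, C, w)
        single = skat(y, C, X, w)
        batched = battery.test(y)
        assert batched.q == pytest.approx(single.q)
        assert batched.p == pytest.approx(single.p, rel=1e-10)


class TestPermutationOracle:
    def test_p_lower_bound(self):
        y, C, X, w = _dataset(seed=10)
        res = skat_permutation(y, C, X, w, n_perm=100, seed=1)
        assert res.p >= 1 / 101

    def test_n_perm_minimum(self):
        y, C, X, w = _dataset(seed=11)
        with pytest.raises(ValueError):
            skat_permutation(y, C, X, w, n_perm=50)

    def test_effect_size_decreases_p(self):
        ps = []
        for effect in (0.0, 0.3, 1.0):
            pvals = [
                skat_permutation(*_dataset(n=300, seed=s, effect=effect), n_perm=300, seed=s).p
                for s in range(4)
            ]
            ps.append(np.mean(pvals))
        assert ps[0] > ps[2]
        assert ps[1] >= ps[2]

    def test_agrees_with_analytic_p(self):
        analytic, perm = [], []
        for s in range(25):
            y, C, X, w = _dataset(n=250, m=12, seed=100 + s, effect=0.05 * (s % 4))
            analytic.append(skat(y, C, X, w).p)
            perm.append(skat_permutation(y, C, X, w, n_perm=400, seed=s).p)
        rho = stats.spearmanr(analytic, perm).statistic
        assert rho > 0.9
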