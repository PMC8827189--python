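"""PGLS, phylogenetic signal, paired t-test, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import thermogc as tg
from thermogc.phylo import ModelParams, model_covariance
from thermogc.stats import _gls_profile, bh_adjust, bh_adjust_grouped
from thermogc.synth import gen_tree

# Published PGLS P values for the eight GC indexes per domain and
# temperature index (inputs for reproducing the adjusted columns; the
# 2.2e-16 entries are the source's reporting floor, used here as input
# literals only).
TABLE2_P = {
    ("bacteria", "Tmax"): [7.1e-4, 0.002, 0.003, 1.7e-4, 2.2e-16, 1.2e-6, 2.2e-16, 2.2e-16],
    ("bacteria", "Topt"): [0.009, 0.015, 0.016, 0.004, 2.6e-14, 1.4e-4, 2.2e-16, 2.2e-16],
    ("bacteria", "Tmin"): [0.156, 0.202, 0.239, 0.170, 9.1e-4, 0.001, 2.2e-16, 2.2e-16],
    ("archaea", "Tmax"): [0.115, 0.183, 0.321, 0.025, 1.8e-11, 1.9e-5, 3.9e-11, 2.2e-16],
    ("archaea", "Topt"): [0.377, 0.522, 0.806, 0.080, 2.5e-7, 1.6e-4, 1.1e-10, 1.2e-14],
    ("archaea", "Tmin"): [0.126, 0.180, 0.393, 0.048, 1.8e-6, 0.005, 8.5e-8, 8.0e-11],
}
TABLE2_P_BH = {
    ("bacteria", "Tmax"): [9.4e-4, 0.002, 0.003, 2.8e-4, 5.9e-16, 2.4e-6, 5.9e-16, 5.9e-16],
    ("bacteria", "Topt"): [0.011, 0.016, 0.016, 0.006, 6.9e-14, 2.9e-4, 8.8e-16, 8.8e-16],
    ("bacteria", "Tmin"): [0.226, 0.231, 0.239, 0.226, 0.002, 0.002, 8.8e-16, 8.8e-16],
    ("archaea", "Tmax"): [0.153, 0.209, 0.321, 0.041, 7.2e-11, 3.9e-5, 1.0e-10, 1.8e-15],
    ("archaea", "Topt"): [0.503, 0.597, 0.806, 0.129, 6.7e-7, 3.2e-4, 4.5e-10, 9.5e-14],
    ("archaea", "Tmin"): [0.168, 0.205, 0.393, 0.077, 4.7e-6, 0.010, 3.4e-7, 6.4e-10],
}


class TestPgls:
    def test_lambda_zero_equals_ols(self, tree50):
        # With lambda forced to 0 on an ultrametric tree the GLS problem
        # collapses to ordinary least squares.
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 1.0 + 2.0 * x + rng.normal(size=50)
        cov = tree50.covariance()
        V0 = model_covariance(cov, ModelParams("lambda", 1.0, lam=0.0))
        X = np.column_stack([np.ones(50), x])
        beta, *_ = _gls_profile(V0, y, X)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    def test_four_tip_closed_form(self, balanced4):
        # beta = (X' V^-1 X)^-1 X' V^-1 y with V assembled by hand.
        y = pd.Series({"A": 1.0, "B": 2.0, "C": 4.0, "D": 7.0})
        x = pd.Series({"A": 0.0, "B": 1.0, "C": 2.0, "D": 3.0})
        V = np.array([[2.0, 1.0, 0.0, 0.0],
                      [1.0, 2.0, 0.0, 0.0],
                      [0.0, 0.0, 2.0, 1.0],
                      [0.0, 0.0, 1.0, 2.0]])
        X = np.column_stack([np.ones(4), [0.0, 1.0, 2.0, 3.0]])
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y.loc[list("ABCD")].to_numpy())
        fit = tg.pgls(balanced4, y, x, model="BM", names=["x"])
        assert fit.coef["intercept"] == pytest.approx(beta[0], rel=1e-10)
        assert fit.coef["x"] == pytest.approx(beta[1], rel=1e-10)

    @pytest.mark.parametrize("model", ["BM", "lambda", "OU_fixed_root", "EB"])
    def test_loglik_matches_mvn_density(self, tree50, model):
        X = tg.simulate_traits(tree50, np.array([[1, 0.5], [0.5, 1]]), seed=3)[0]
        fit = tg.pgls(tree50, X[:, 1], X[:, 0], model=model, names=["x"])
        cov = tree50.covariance()
        if model == "BM":
            params = ModelParams("BM", 1.0)
        elif model == "lambda":
            params = ModelParams("lambda", 1.0, lam=fit.param)
        elif model == "OU_fixed_root":
            params = ModelParams("OU_fixed_root", 1.0, alpha=fit.param)
        else:
            params = ModelParams("EB", 1.0, r=fit.param)
        V = fit.sigma2 * model_covariance(cov, params)
        mean = fit.coef["intercept"] + fit.coef["x"] * X[:, 0]
        direct = sps.multivariate_normal.logpdf(X[:, 1], mean=mean, cov=V)
        assert fit.loglik == pytest.approx(direct, abs=1e-6)

    def test_aic_ranking_invariant_to_affine_y(self, tree50):
        X = tg.simulate_traits(tree50, np.array([[1, 0.4], [0.4, 1]]), seed=4)[0]
        models = ["BM", "lambda", "OU_fixed_root", "EB"]
        y1 = pd.Series(X[:, 1], index=tree50.tip_labels)
        y2 = 10.0 + 3.0 * y1
        x = pd.Series(X[:, 0], index=tree50.tip_labels)
        fits1 = {m: tg.pgls(tree50, y1, x, model=m, names=["x"]) for m in models}
        fits2 = {m: tg.pgls(tree50, y2, x, model=m, names=["x"]) for m in models}
        rank1 = sorted(models, key=lambda m: fits1[m].aic)
        rank2 = sorted(models, key=lambda m: fits2[m].aic)
        assert rank1 == rank2
        for m in models:
            assert fits2[m].coef["x"] == pytest.approx(3.0 * fits1[m].coef["x"],
                                                       rel=1e-4)

    def test_multiple_predictors(self, tree100):
        rng = np.random.default_rng(5)
        X = tg.simulate_traits(tree100, np.array([[1, 0.5], [0.5, 1]]), seed=6)[0]
        binary = pd.Series(rng.integers(0, 2, 100), index=tree100.tip_labels,
                           dtype=float)
        design = pd.DataFrame({"Topt": X[:, 0], "domain": binary},
                              index=tree100.tip_labels)
        fit = tg.pgls(tree100, pd.Series(X[:, 1], index=tree100.tip_labels),
                      design, model="lambda")
        assert set(fit.coef) == {"intercept", "Topt", "domain"}
        assert 0 < fit.pvals["domain"] <= 1

    def test_missing_tips_dropped_not_imputed(self, tree50):
        y = pd.Series(np.arange(45, dtype=float) + np.random.default_rng(1).normal(size=45),
                      index=tree50.tip_labels[:45])
        x = pd.Series(np.arange(50, dtype=float), index=tree50.tip_labels)
        fit = tg.pgls(tree50, y, x, model="BM", names=["x"])
        assert fit.n == 45

    def test_singular_design_rejected(self, tree50):
        x = pd.Series(np.ones(50), index=tree50.tip_labels)
        y = pd.Series(np.random.default_rng(2).normal(size=50), index=tree50.tip_labels)
        with pytest.raises(np.linalg.LinAlgError):
            tg.pgls(tree50, y, x, model="BM", names=["x"])


class TestPagelSignal:
    def test_grid_vs_optimizer(self):
        # continuous optimizer agrees with a fine grid search within 0.01
        for seed in range(20):
            tree = gen_tree(n_tips=40, seed=100 + seed)
            x = tg.simulate_traits(tree, np.eye(2), seed=seed)[0][:, 0]
            est = tg.pagel_lambda_signal(tree, x)
            cov = tree.covariance()
            Xm = np.ones((40, 1))
            grid = np.linspace(0, 1, 101)
            lls = [_gls_profile(model_covariance(cov, ModelParams("lambda", 1.0, lam=g)),
                                x, Xm)[2] for g in grid]
            lam_grid = grid[int(np.argmax(lls))]
            assert abs(est.lam - lam_grid) <= 0.01

    def test_constant_trait_rejected(self, tree50):
        with pytest.raises(ValueError, match="constant"):
            tg.pagel_lambda_signal(tree50, np.ones(50))

    def test_star_tree_flat_likelihood(self):
        star = tg.read_newick("(A:1,B:1,C:1,D:1,E:1);")
        est = tg.pagel_lambda_signal(star, np.array([1.0, 2.0, 3.0, 4.0, 8.0]))
        assert est.lam == 0.0
        assert est.pvalue == 1.0

    def test_signal_bounds_and_lrt(self, tree100):
        x = tg.simulate_traits(tree100, np.eye(2), seed=8)[0][:, 0]
        est = tg.pagel_lambda_signal(tree100, x)
        assert 0.0 <= est.lam <= 1.0
        assert est.loglik >= est.loglik0
        assert 0 < est.pvalue <= 1


class TestPairedTTest:
    def test_identical_traits(self, tree50):
        x = pd.Series(np.arange(50, dtype=float), index=tree50.tip_labels)
        res = tg.phylo_paired_ttest(tree50, x, x)
        assert res.mean_diff == 0.0 and res.tstat == 0.0 and res.pvalue == 1.0

    def test_null_calibration(self):
        tree = gen_tree(n_tips=100, seed=30)
        hits = 0
        reps = 200
        for rep in range(reps):
            d = tg.simulate_traits(tree, np.eye(2), seed=500 + rep)[0][:, 0]
            x2 = pd.Series(np.zeros(100), index=tree.tip_labels)
            res = tg.phylo_paired_ttest(tree, pd.Series(d, index=tree.tip_labels), x2)
            hits += res.pvalue < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_planted_offset_power(self):
        tree = gen_tree(n_tips=100, seed=31)
        for rep in range(20):
            d = tg.simulate_traits(tree, 0.01 * np.eye(2), seed=700 + rep)[0][:, 0] + 5.0
            x2 = pd.Series(np.zeros(100), index=tree.tip_labels)
            res = tg.phylo_paired_ttest(tree, pd.Series(d, index=tree.tip_labels), x2)
            assert res.pvalue < 1e-3


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_named_cells_from_published_families(self):
        bact = bh_adjust(TABLE2_P[("bacteria", "Tmax")])
        assert bact[0] == pytest.approx(9.4e-4, rel=0.01)
        arch = bh_adjust(TABLE2_P[("archaea", "Tmax")])
        assert arch[0] == pytest.approx(0.153, rel=0.005)

    def test_all_published_cells_reproduced(self):
        # Exact up to the rounding of the published input P values.
        for key, ps in TABLE2_P.items():
            adj = bh_adjust(ps)
            np.testing.assert_allclose(adj, TABLE2_P_BH[key], rtol=0.15)

    def test_monotone_in_sorted_order_and_capped(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-6, 1, 30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)

    def test_step_up_formula(self):
        # adj_(k) = min_{j >= k} p_(j) m / j, capped at 1
        p = np.array([0.04, 0.9, 0.01, 0.03])
        expected = []
        order = np.argsort(p)
        sp = p[order]
        m = len(p)
        for k in range(m):
            expected.append(min(min(sp[j] * m / (j + 1) for j in range(k, m)), 1.0))
        out = bh_adjust(p)
        np.testing.assert_allclose(out[order], expected)

    @pytest.mark.parametrize("bad", [[0.0], [1.2], [-0.1], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    def test_grouped_adjustment(self):
        rows = []
        for (dom, t), ps in TABLE2_P.items():
            for i, p in enumerate(ps):
                rows.append({"domain": dom, "temp": t, "gc_index": i, "P": p})
        df = bh_adjust_grouped(pd.DataFrame(rows), "P", ["domain", "temp"])
        sub = df[(df.domain == "bacteria") & (df.temp == "Tmax")]
        np.testing.assert_allclose(sub["P_BH"].to_numpy(),
                                   bh_adjust(TABLE2_P[("bacteria", "Tmax")]))
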