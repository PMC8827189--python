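"""Levy-jump simulation, Monte-Carlo likelihood, posteriors, correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import thermogc as tg
from thermogc.jumps import (JumpParams, _TreeCache, bm_loglik,
                            branch_jump_posteriors, mc_loglik, simulate_levy,
                            spearman_exact)
from thermogc.synth import gen_tree


class TestSimulateLevy:
    def test_pure_bm_tip_covariance(self):
        tree = gen_tree(n_tips=5, seed=50)
        C = tree.covariance().C
        reps = np.array([
            simulate_levy(tree, 1.0, 0.0, 0.0, 0.0, seed=s)[0]
            .loc[tree.tip_labels].to_numpy()
            for s in range(5000)])
        S = np.cov(reps, rowvar=False)
        assert np.linalg.norm(S - C) / np.linalg.norm(C) < 0.07

    def test_single_branch_total_variance(self):
        # law of total variance: var = sigma2 t + lam t sigma2_j
        tree = tg.read_newick("(A:2,B:2);")
        s2, lam, sj2 = 1.0, 1.5, 4.0
        vals = np.array([simulate_levy(tree, s2, lam, sj2, 0.0, seed=s)[0]["A"]
                         for s in range(10_000)])
        expected = s2 * 2 + lam * 2 * sj2
        assert vals.var() == pytest.approx(expected, rel=0.05)

    def test_poisson_mean_jump_count(self, tree50):
        lam = 0.8
        total = tree50.total_length()
        counts = [simulate_levy(tree50, 0.0, lam, 1.0, 0.0, seed=s)[1]["n_jumps"].sum()
                  for s in range(3000)]
        assert np.mean(counts) == pytest.approx(lam * total, rel=0.03)

    def test_truth_indexed_by_branch(self, tree50):
        _, truth = simulate_levy(tree50, 1.0, 1.0, 1.0, 0.0, seed=0)
        assert set(truth.index) == {b.id for b in tree50.branches()}


class TestMcLoglik:
    def test_no_jumps_equals_bm_closed_form(self, tree100):
        tips, _ = simulate_levy(tree100, 1.0, 0.0, 0.0, 2.0, seed=1)
        cache = _TreeCache(tree100)
        y = tips.loc[tree100.tip_labels].to_numpy()
        for params in (JumpParams(1.3, 0.0, 5.0, 2.0), JumpParams(1.3, 0.7, 0.0, 2.0)):
            ll, se = mc_loglik(tree100, tips, params, M=200, seed=0)
            res = y - params.mu0
            quad = float(res @ cache.solve(res)) / params.sigma2
            exact = -0.5 * (len(y) * math.log(2 * math.pi * params.sigma2)
                            + cache.logdetC + quad)
            assert ll == pytest.approx(exact, abs=1e-9)
            assert se == 0.0

    def test_three_tip_truncated_enumeration(self, three_tip):
        # Exact marginal by enumerating k_b in {0,1,2} on all four branches.
        params = JumpParams(0.5, 0.4, 2.0, 1.0)
        tips, _ = simulate_levy(three_tip, 0.5, 0.4, 2.0, 1.0, seed=3)
        y = tips.loc[three_tip.tip_labels].to_numpy()
        cache = _TreeCache(three_tip)
        branches = three_tip.branches()
        exact = 0.0
        for ks in itertools.product(range(3), repeat=len(branches)):
            prior = np.prod([sps.poisson.pmf(k, params.lam_j * b.length)
                             for k, b in zip(ks, branches)])
            V = params.sigma2 * cache.C.copy()
            for k, b in zip(ks, branches):
                if k:
                    m = np.zeros(3)
                    m[b.tip_indices] = 1.0
                    V += params.sigma2_j * k * np.outer(m, m)
            dens = sps.multivariate_normal.pdf(y, mean=np.full(3, params.mu0), cov=V)
            exact += prior * dens
        ll_exact = math.log(exact)
        ll, se = mc_loglik(three_tip, tips, params, M=20_000, seed=4)
        assert abs(ll - ll_exact) <= 3 * max(se, 1e-6) + 1e-3

    def test_mc_se_shrinks_as_sqrt_m(self, tree50):
        # Moderate jump intensity (~0.5 expected jumps per draw) keeps the
        # importance weights light-tailed, where the CLT 1/sqrt(M) scaling
        # of the Monte-Carlo standard error is visible.
        lam = 0.5 / tree50.total_length()
        tips, _ = simulate_levy(tree50, 1.0, lam, 2.0, 0.0, seed=5)
        params = JumpParams(1.0, lam, 2.0, 0.0)
        ses = [np.mean([mc_loglik(tree50, tips, params, M=M, seed=s)[1]
                        for s in range(20)])
               for M in (100, 1000, 10_000)]
        assert ses[0] > ses[1] > ses[2]
        # ratio close to sqrt(10) per decade
        assert 2.0 < ses[0] / ses[1] < 5.0
        assert 2.0 < ses[1] / ses[2] < 5.0

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            JumpParams(-1.0, 0.0, 0.0, 0.0)


class TestPosteriors:
    def test_planted_jump_found(self, tree100):
        brs = [b for b in tree100.branches()
               if not b.child_is_tip and 5 <= len(b.tip_indices) <= 40]
        br = max(brs, key=lambda b: b.length)
        y = tg.simulate_traits(tree100, np.eye(2), seed=60)[0][:, 0]
        y[br.tip_indices] += 10.0
        params = JumpParams(1.0, 2.0 / tree100.total_length(), 100.0, 0.0)
        pp, ess = branch_jump_posteriors(tree100, y, params, M=2000, seed=1)
        assert max(pp, key=pp.get) == br.id
        assert pp[br.id] > 0.8

    def test_reproducible_from_seed(self, tree100):
        y = tg.simulate_traits(tree100, np.eye(2), seed=61)[0][:, 0]
        params = JumpParams(1.0, 0.5, 4.0, 0.0)
        pp1, _ = branch_jump_posteriors(tree100, y, params, M=500, seed=2)
        pp2, _ = branch_jump_posteriors(tree100, y, params, M=500, seed=2)
        assert pp1 == pp2

    def test_pp_in_unit_interval_and_prior_scale(self, tree100):
        # without jumps in the data, mean pp stays within +-50% of the
        # Poisson prior probability of >= 1 jump, averaged over branches
        tips, _ = simulate_levy(tree100, 1.0, 0.0, 0.0, 0.0, seed=6)
        lam = 1.0 / tree100.total_length()
        params = JumpParams(1.0, lam, 0.5, 0.0)
        pp, _ = branch_jump_posteriors(tree100, tips, params, M=3000, seed=3)
        vals = np.array(list(pp.values()))
        assert ((vals >= 0) & (vals <= 1)).all()
        prior = np.mean([1 - math.exp(-lam * b.length) for b in tree100.branches()])
        assert 0.5 * prior < vals.mean() < 1.5 * prior


class TestCalibration:
    def test_curve_endpoints(self, tree50):
        params = JumpParams(1.0, 1.0, 9.0, 0.0)
        curve, thr = tg.calibrate_threshold(tree50, params, n_sims=3,
                                            pp_grid=[0.0, 0.5, 1.0 + 1e-9],
                                            seed=0, M=300)
        assert curve.loc[curve.threshold == 0.0, "recall"].item() == 1.0
        top = curve.loc[curve.threshold > 1.0]
        assert math.isnan(top["precision"].item())
        assert top["n_called"].item() == 0

    def test_precision_recall_tradeoff(self, tree50):
        params = JumpParams(1.0, 1.0, 9.0, 0.0)
        curve, _ = tg.calibrate_threshold(tree50, params, n_sims=5, seed=1, M=300)
        ok = curve.dropna(subset=["precision"])
        # after monotone cleanup precision is nonincreasing in recall
        order = ok.sort_values("recall")
        cleaned = order["precision"].cummax()[::-1]
        assert (np.diff(order["recall"]) >= 0).all()
        assert (np.diff(cleaned[::-1]) >= -1e-12).all()


class TestSpearmanAndJumpChanges:
    def test_monotone_gives_rho_one(self, tree50):
        brs = [b.id for b in tree50.branches()][:8]
        anc = {b.id: b for b in tree50.branches()}
        x = tg.simulate_traits(tree50, np.eye(2), seed=70)[0][:, 0]
        n, rho, p, tab = tg.jump_change_correlation(
            tree50, dict(zip(tree50.tip_labels, x)),
            dict(zip(tree50.tip_labels, 2.0 * x + 1.0)), brs)
        assert n == 8
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(8), rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_permutation_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, p = spearman_exact(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rx_c = rx - rx.mean()
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(ry))
        assert p == pytest.approx(count / math.factorial(8))
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic)

    def test_needs_five_branches(self, tree50):
        x = dict(zip(tree50.tip_labels, range(50)))
        with pytest.raises(ValueError):
            tg.jump_change_correlation(tree50, x, x,
                                       [b.id for b in tree50.branches()][:3])


class TestModelComparison:
    def test_bm_aic_uses_closed_form(self, tree100):
        tips, _ = simulate_levy(tree100, 2.0, 0.0, 0.0, 1.0, seed=7)
        ll, params = bm_loglik(tree100, tips.loc[tree100.tip_labels].to_numpy())
        cov = tree100.covariance()
        V = params.sigma2 * cov.C
        direct = sps.multivariate_normal.logpdf(
            tips.loc[tree100.tip_labels].to_numpy(),
            mean=np.full(100, params.mu0), cov=V)
        assert ll == pytest.approx(direct, abs=1e-6)

    def test_fit_recovers_jump_signal(self, tree100):
        tips, truth = simulate_levy(tree100, 1.0, 0.3, 25.0, 0.0, seed=8)
        fit = tg.fit_jump_model(tree100, tips, M=200, seed=0)
        assert fit.aic < fit.bm_aic  # obvious jumps: jump model wins
        assert all(0 <= v <= 1 for v in fit.pp.values())
        assert fit.params.sigma2 > 0
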