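"""Blomberg's K, Pagel's λ, null tests, and multiple-testing adjustments.

Oracles are dense-matrix implementations written directly from the defining
formulas with explicit inverses, independent of the factorization-based
production path.
"""

import numpy as np
import pytest

import phylofa as pf
from phylofa.signal import _fit_sigma2, _neg_loglik_sigma2


def _k_oracle(x, C):
    """Explicit-inverse K, straight from the definition."""
    n = len(x)
    invC = np.linalg.inv(C)
    one = np.ones(n)
    a = (one @ invC @ x) / (one @ invC @ one)
    r = x - a
    mse0 = r @ r / (n - 1)
    mse = r @ invC @ r / (n - 1)
    er = (np.trace(C) - n / (one @ invC @ one)) / (n - 1)
    return (mse0 / mse) / er, a


def _loglik_lambda_oracle(x, C, lam):
    """Dense profile log-likelihood at a fixed λ."""
    n = len(x)
    Cl = lam * C + (1 - lam) * np.diag(np.diag(C))
    invCl = np.linalg.inv(Cl)
    one = np.ones(n)
    a = (one @ invCl @ x) / (one @ invCl @ one)
    r = x - a
    s2 = r @ invCl @ r / n
    sign, logdet = np.linalg.slogdet(Cl)
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


class TestPhyloMean:
    def test_identity_reduces_to_arithmetic_mean(self, rng):
        x = rng.normal(size=6)
        assert pf.phylo_mean(x, np.eye(6)) == pytest.approx(x.mean())

    def test_constant_trait_recovered(self, three_tip):
        cov = pf.phylo_covariance(three_tip)
        assert pf.phylo_mean(np.full(3, 7.5), cov) == pytest.approx(7.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_linear_solve_oracle(self, seed):
        tree = pf.yule_tree(4, seed=seed)
        C = pf.phylo_covariance(tree).C
        x = np.random.default_rng(seed).normal(size=4)
        invC = np.linalg.inv(C)
        one = np.ones(4)
        expected = (one @ invC @ x) / (one @ invC @ one)
        assert pf.phylo_mean(x, C) == pytest.approx(expected, abs=1e-12)


class TestBlombergK:
    def test_equal_depth_star_is_one(self, star_tree, rng):
        cov = pf.phylo_covariance(star_tree)
        for _ in range(5):
            x = rng.normal(size=5)
            assert pf.blomberg_k(x, cov).K == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        tree = pf.yule_tree(10, seed=3)
        cov = pf.phylo_covariance(tree)
        x = rng.normal(size=10)
        k0 = pf.blomberg_k(x, cov).K
        assert pf.blomberg_k(3.2 * x - 11.0, cov).K == pytest.approx(k0, abs=1e-10)

    def test_branch_rescaling_invariance(self, rng):
        tree = pf.yule_tree(8, seed=5)
        cov = pf.phylo_covariance(tree)
        x = rng.normal(size=8)
        scaled = pf.PhyloCovariance(cov.C * 7.3, cov.taxa)
        assert pf.blomberg_k(x, scaled).K == pytest.approx(pf.blomberg_k(x, cov).K, abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_explicit_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = pf.yule_tree(6, seed=seed)
        cov = pf.phylo_covariance(tree)
        x = rng.normal(size=6)
        res = pf.blomberg_k(x, cov)
        k_exp, a_exp = _k_oracle(x, cov.C)
        assert res.K == pytest.approx(k_exp, abs=1e-10)
        assert res.a_hat == pytest.approx(a_exp, abs=1e-10)

    def test_degenerate_inputs_rejected(self, three_tip):
        cov = pf.phylo_covariance(three_tip)
        with pytest.raises(ValueError):
            pf.blomberg_k(np.ones(3), cov)
        with pytest.raises(ValueError):
            pf.blomberg_k(np.array([1.0, 2.0]), np.eye(2))


class TestKWithMeasurementError:
    def test_zero_se_reduces_to_plain(self, rng):
        tree = pf.yule_tree(10, seed=1)
        cov = pf.phylo_covariance(tree)
        x = rng.normal(size=10)
        plain = pf.blomberg_k(x, cov)
        with_se = pf.blomberg_k_with_se(x, np.zeros(10), cov)
        assert with_se.K == plain.K
        assert with_se.sigma2_hat is None

    def test_sigma2_matches_grid_search_oracle(self):
        tree = pf.yule_tree(5, seed=2)
        cov = pf.phylo_covariance(tree)
        rng = np.random.default_rng(2)
        x = pf.simulate_bm(tree, 1.0, 1, seed=3)[:, 0]
        se = np.abs(rng.normal(0.3, 0.1, size=5))
        res = pf.blomberg_k_with_se(x, se, cov)
        # oracle: fine grid over the same admissible interval
        invC = np.linalg.inv(cov.C)
        one = np.ones(5)
        a0 = (one @ invC @ x) / (one @ invC @ one)
        s2_hi = (x - a0) @ invC @ (x - a0) / 5
        grid = np.exp(np.linspace(np.log(s2_hi) - 18.5, np.log(s2_hi), 400001))
        vals = [_neg_loglik_sigma2(s, x, cov.C, se**2) for s in grid]
        s2_grid = grid[int(np.argmin(vals))]
        assert res.sigma2_hat == pytest.approx(s2_grid, rel=1e-4)

    def test_accounting_for_noise_pulls_k_toward_one(self):
        """BM traits measured with replicate noise: the error-adjusted K is
        less attenuated than the naive K that ignores the noise."""
        tree = pf.yule_tree(40, seed=7)
        cov = pf.phylo_covariance(tree)
        rng = np.random.default_rng(7)
        n_rep = 300
        k_naive, k_adj = [], []
        se = np.full(40, 0.5)
        for i in range(n_rep):
            latent = pf.simulate_bm(tree, 1.0, 1, seed=rng)[:, 0]
            x = latent + rng.normal(0, 0.5, size=40)
            k_naive.append(pf.blomberg_k(x, cov).K)
            k_adj.append(pf.blomberg_k_with_se(x, se, cov).K)
        assert abs(np.mean(k_adj) - 1) < abs(np.mean(k_naive) - 1)

    def test_negative_se_rejected(self, three_tip):
        cov = pf.phylo_covariance(three_tip)
        with pytest.raises(ValueError):
            pf.blomberg_k_with_se(np.array([1.0, 2.0, 3.0]), np.array([0.1, -0.1, 0.1]), cov)


class TestPermutationTest:
    def test_p_bounds_and_determinism(self, rng):
        tree = pf.yule_tree(12, seed=4)
        cov = pf.phylo_covariance(tree)
        x = rng.normal(size=12)
        p1 = pf.permutation_test_k(x, None, cov, n_perm=99, seed=5)
        p2 = pf.permutation_test_k(x, None, cov, n_perm=99, seed=5)
        assert p1 == p2
        assert 1 / 100 <= p1 <= 1.0

    def test_strong_bm_trait_detected(self):
        # deep balanced tree: BM traits should almost always look significant
        tree = pf.yule_tree(32, seed=6)
        cov = pf.phylo_covariance(tree)
        hits = 0
        for seed in range(10):
            x = pf.simulate_bm(tree, 1.0, 1, seed=seed)[:, 0]
            p = pf.permutation_test_k(x, None, cov, n_perm=199, seed=seed)
            hits += p <= 0.05
        assert hits >= 8

    def test_with_se_runs_and_is_seeded(self, rng):
        tree = pf.yule_tree(8, seed=9)
        cov = pf.phylo_covariance(tree)
        x = rng.normal(size=8)
        se = np.abs(rng.normal(0.2, 0.05, size=8))
        p1 = pf.permutation_test_k(x, se, cov, n_perm=49, seed=1)
        p2 = pf.permutation_test_k(x, se, cov, n_perm=49, seed=1)
        assert p1 == p2


class TestBMSimulationTest:
    def test_k_of_one_is_consistent_with_bm(self):
        tree = pf.yule_tree(32, seed=0)
        p, q025, q975, cls = pf.bm_simulation_test(1.0, tree, n_sim=500, seed=0)
        assert q025 <= 1.0 <= q975
        assert cls == "consistent"
        assert p > 0.05

    def test_extreme_k_classified(self):
        tree = pf.yule_tree(32, seed=0)
        p_hi, *_, cls_hi = pf.bm_simulation_test(50.0, tree, n_sim=500, seed=0)
        p_lo, *_, cls_lo = pf.bm_simulation_test(1e-3, tree, n_sim=500, seed=0)
        assert cls_hi == "higher" and cls_lo == "lower"
        assert p_hi <= 0.05 and p_lo <= 0.05

    def test_small_nsim_warns(self, three_tip):
        with pytest.warns(UserWarning):
            pf.bm_simulation_test(1.0, three_tip, n_sim=50, seed=0)

    def test_invalid_k_rejected(self, three_tip):
        with pytest.raises(ValueError):
            pf.bm_simulation_test(0.0, three_tip, n_sim=200, seed=0)


class TestPagelLambda:
    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_matches_dense_oracle_on_grid(self, seed):
        tree = pf.yule_tree(7, seed=seed)
        cov = pf.phylo_covariance(tree)
        x = np.random.default_rng(seed).normal(size=7)
        from phylofa.signal import _lambda_profile_loglik

        Cdiag = np.diag(cov.C).copy()
        Coff = cov.C - np.diag(Cdiag)
        for lam in np.linspace(0, 1, 10):
            got = _lambda_profile_loglik(lam, x, Coff, Cdiag)[0]
            assert got == pytest.approx(_loglik_lambda_oracle(x, cov.C, lam), abs=1e-10)

    def test_logl_dominates_null_and_unit_lambda(self, rng):
        tree = pf.yule_tree(20, seed=3)
        x = pf.simulate_bm(tree, 1.0, 1, seed=3)[:, 0]
        res = pf.pagel_lambda_ml(x, tree)
        assert res.logL >= res.logL0 - 1e-9
        cov = pf.phylo_covariance(tree)
        from phylofa.signal import _lambda_profile_loglik

        Cdiag = np.diag(cov.C).copy()
        at_one = _lambda_profile_loglik(1.0, x, cov.C - np.diag(Cdiag), Cdiag)[0]
        assert res.logL >= at_one - 1e-9

    def test_star_tree_reports_flat_likelihood(self, rng):
        star = pf.parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        x = rng.normal(size=6)
        res = pf.pagel_lambda_ml(x, star)
        assert res.flat_likelihood
        assert np.isnan(res.lam_hat)
        assert res.p_lr == 1.0

    def test_upper_bound_flagged(self):
        # strong BM on a small tree often drives λ̂ to its ceiling
        tree = pf.yule_tree(40, seed=11)
        x = pf.simulate_bm(tree, 1.0, 1, seed=12)[:, 0]
        res = pf.pagel_lambda_ml(x, tree)
        assert 0 <= res.lam_hat <= res.lam_max
        assert res.at_upper_bound == (res.lam_hat >= res.lam_max - 1e-6)

    def test_constant_trait_rejected(self, three_tip):
        with pytest.raises(ValueError):
            pf.pagel_lambda_ml(np.ones(3), three_tip)


class TestAdjustmentsAndDecision:
    def test_single_p_unchanged(self):
        assert pf.bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert pf.holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_bh_stepup(self):
        np.testing.assert_allclose(
            pf.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_holm_stepdown(self):
        np.testing.assert_allclose(pf.holm_adjust([0.01, 0.04]), [0.02, 0.04], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pf.bh_adjust([0.5, 1.2])

    def test_dual_decision_logic(self):
        k = pf.KResult(K=1.5, MSE0=1, MSE=1, expected_ratio=1, a_hat=0)
        lam = pf.LambdaResult(lam_hat=1, sigma2_hat=1, a_hat=0, logL=0, logL0=-5, p_lr=0.001)
        k.p_perm_adj, lam.p_lr_adj = 0.003, 0.0005
        assert pf.dual_decision(k, lam).signal_present
        k.p_perm_adj = 0.07
        assert not pf.dual_decision(k, lam).signal_present
        k.p_perm_adj, lam.p_lr_adj = 0.05, 0.05
        assert not pf.dual_decision(k, lam, alpha=0.05).signal_present
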