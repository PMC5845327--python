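"""Covariance stitching, Probit inversion, orthant prior assembly."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import hteqtl as ht
from hteqtl.assemble import (_orthant_masses_exact, _orthant_masses_mc,
                             _corr_or_project)
from hteqtl.pairwise import PairwiseFit


def random_correlation(rng, K, jitter=None):
    A = rng.standard_normal((K, K))
    return ht.nearest_correlation(A @ A.T + (jitter or K) * np.eye(K))


def rectangle_oracle(Omega, tau, gamma):
    """Independent rectangle probability via scipy's lower/upper MVN CDF."""
    gamma = np.asarray(gamma, dtype=bool)
    lower = np.where(gamma, tau, -np.inf)
    upper = np.where(gamma, np.inf, tau)
    return multivariate_normal.cdf(
        upper, cov=Omega, lower_limit=lower, abseps=1e-10, releps=0,
        maxpts=2_000_000, rng=np.random.default_rng(99))


class TestNearestCorrelation:
    def test_valid_input_is_fixed_point(self, rng):
        R = random_correlation(rng, 4)
        assert np.allclose(ht.nearest_correlation(R), R, atol=1e-12)

    def test_indefinite_input_projected(self):
        M = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        R = ht.nearest_correlation(M)
        assert np.linalg.eigvalsh(R).min() >= -1e-10
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)

    def test_matches_independent_clip_rescale_oracle(self, rng):
        A = rng.standard_normal((5, 5))
        M = (A + A.T) / 2
        np.fill_diagonal(M, 1.0)
        w, V = np.linalg.eigh(M)
        B = V @ np.diag(np.maximum(w, 0)) @ V.T
        D = np.diag(1 / np.sqrt(np.diag(B)))
        oracle = D @ B @ D
        np.fill_diagonal(oracle, 1.0)
        assert np.allclose(ht.nearest_correlation(M), oracle, atol=1e-10)


class TestAssembleDeltaSigma:
    def _fit(self, i, j, p, delta, sigma):
        return PairwiseFit((i, j), p, delta, np.asarray(sigma, float))

    def test_k2_direct_placement(self):
        f = self._fit(0, 1, [0.9, 0.03, 0.03, 0.04], 0.35, [[4, 2], [2, 5]])
        D = ht.assemble_delta([f])
        assert np.allclose(D, [[1, 0.35], [0.35, 1]])
        S = ht.assemble_sigma([f])
        assert np.allclose(np.diag(S), [4, 5])

    def test_zero_deltas_give_identity(self):
        fits = [self._fit(i, j, [0.9, 0.03, 0.03, 0.04], 0.0,
                          [[2, 1], [1, 2]])
                for i in range(3) for j in range(i + 1, 3)]
        assert np.allclose(ht.assemble_delta(fits), np.eye(3))

    def test_sigma_diagonal_takes_minimum(self):
        # tissue 0 pairwise variance estimates: 4.1, 3.9, 4.3
        vals = {(0, 1): (4.1, 5.0), (0, 2): (3.9, 5.0), (0, 3): (4.3, 5.0),
                (1, 2): (5.0, 5.0), (1, 3): (5.0, 5.0), (2, 3): (5.0, 5.0)}
        fits = [self._fit(i, j, [0.9, 0.03, 0.03, 0.04], 0.0,
                          [[a, 0.5 * np.sqrt(a * b)],
                           [0.5 * np.sqrt(a * b), b]])
                for (i, j), (a, b) in vals.items()]
        S = ht.assemble_sigma(fits)
        assert S[0, 0] == pytest.approx(3.9)

    def test_missing_pair_rejected(self):
        f = self._fit(0, 1, [0.9, 0.03, 0.03, 0.04], 0.0, [[2, 1], [1, 2]])
        g = self._fit(0, 2, [0.9, 0.03, 0.03, 0.04], 0.0, [[2, 1], [1, 2]])
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            ht.assemble_delta([f, g])

    def test_recovery_from_k4_fits(self, k4_est, k4_model):
        assert np.abs(k4_est.delta_ - k4_model.Delta).max() <= 0.03
        rel = np.abs(k4_est.sigma_ - k4_model.Sigma) / np.abs(k4_model.Sigma)
        assert rel.max() <= 0.15


class TestProbitInversion:
    def test_uniform_table_gives_independence_at_median(self):
        pp = ht.probit_invert_pair([0.25, 0.25, 0.25, 0.25])
        assert (pp.tau1, pp.tau2, pp.omega) == (0.0, 0.0, 0.0)

    def test_product_table_gives_zero_omega(self):
        a, b = norm.sf(0.8), norm.sf(-0.3)
        p2 = [(1 - a) * (1 - b), (1 - a) * b, a * (1 - b), a * b]
        pp = ht.probit_invert_pair(p2)
        assert pp.omega == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_against_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tau1, tau2 = rng.normal(1.0, 0.5, size=2)
        omega = rng.uniform(0.05, 0.9)
        # forward orthant table via an independent scipy MVN rectangle
        Om = np.array([[1, omega], [omega, 1]])
        p11 = rectangle_oracle(Om, np.array([tau1, tau2]), [1, 1])
        p01 = norm.sf(tau2) - p11
        p10 = norm.sf(tau1) - p11
        p2 = [1 - p01 - p10 - p11, p01, p10, p11]
        pp = ht.probit_invert_pair(p2)
        assert pp.tau1 == pytest.approx(tau1, abs=1e-4)
        assert pp.tau2 == pytest.approx(tau2, abs=1e-4)
        assert pp.omega == pytest.approx(omega, abs=1e-4)

    def test_incoherent_p11_clamped_with_warning(self):
        # p11 far below the independence orthant of its margins
        p2 = [0.5, 0.2495, 0.2495, 0.001]
        with pytest.warns(RuntimeWarning, match="clamped"):
            pp = ht.probit_invert_pair(p2)
        assert pp.omega == 0.0


class TestOrthantPrior:
    def test_k2_independent_fair_coins(self):
        pairs = [ht.ProbitPair((0, 1), 0.0, 0.0, 0.0)]
        _, tau, (configs, probs) = ht.assemble_prior(pairs, 2, trunc=1e-5)
        assert np.allclose(probs, 0.25, atol=1e-12)
        assert len(probs) == 4

    def test_univariate_tail_probability(self):
        tau = norm.ppf(0.9)
        masses = _orthant_masses_exact(np.eye(1), np.array([tau]))
        assert masses[0] == pytest.approx(0.9, abs=1e-12)
        assert masses[1] == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("K", [2, 3, 4, 5, 6, 7, 8])
    def test_masses_sum_to_one(self, K):
        rng = np.random.default_rng(K)
        Om = random_correlation(rng, K)
        tau = rng.normal(1.0, 0.5, K)
        masses = _orthant_masses_exact(Om, tau)
        assert abs(masses.sum() - 1.0) < 1e-8

    def test_masses_match_rectangle_oracle(self):
        rng = np.random.default_rng(2)
        Om = random_correlation(rng, 4)
        tau = rng.normal(0.8, 0.4, 4)
        masses = _orthant_masses_exact(Om, tau)
        for g in [(0, 0, 0, 0), (1, 0, 1, 0), (1, 1, 1, 1)]:
            code = int("".join(map(str, g)), 2)
            assert masses[code] == pytest.approx(
                rectangle_oracle(Om, tau, g), abs=5e-6)

    def test_montecarlo_matches_quadrature(self):
        """Equicorrelated K=3 at omega=0.5, tau=1: the one-sweep MC tally
        agrees with per-configuration quadrature within 3 binomial SEs."""
        Om = np.full((3, 3), 0.5)
        np.fill_diagonal(Om, 1.0)
        tau = np.ones(3)
        exact = _orthant_masses_exact(Om, tau)
        n = 2_000_000
        mc = _orthant_masses_mc(Om, tau, n, seed=17)
        se = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(mc - exact) <= 3 * se + 1e-9)

    def test_truncation_contract(self, k4_est):
        model = k4_est.model_
        assert model.support_size <= 2 ** model.K
        assert model.probs.min() >= model.trunc / (1 + 1e-12)
        assert model.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_method_dimension_guard(self):
        pairs = [ht.ProbitPair((i, j), 1.0, 1.0, 0.3)
                 for i in range(16) for j in range(i + 1, 16)]
        with pytest.raises(ValueError, match="montecarlo"):
            ht.assemble_prior(pairs, 16, method="exact")


class TestAssembleModel:
    def test_k2_self_consistency(self):
        """For K=2 the assembled prior must reproduce the pairwise table
        (Probit round trip)."""
        p2 = np.array([0.80, 0.05, 0.05, 0.10])
        fit = PairwiseFit((0, 1), p2, 0.2, np.array([[4.0, 3.0], [3.0, 4.0]]))
        model = ht.assemble_model([fit], trunc=1e-7)
        tv = 0.5 * sum(
            abs(model.prob_of([u, v]) - p2[2 * u + v])
            for u in (0, 1) for v in (0, 1))
        assert tv < 1e-3

    def test_k9_prior_recovery(self, k9_est, k9_model):
        """Assembled support covers the generating configurations and the
        prior is close in KL divergence."""
        est_support = set(map(tuple, k9_est.model_.configs.tolist()))
        for cfg, pr in zip(k9_model.configs, k9_model.probs):
            if pr >= 1e-3:
                assert tuple(int(b) for b in cfg) in est_support
        kl = ht.kl_divergence(k9_model, k9_est.model_)
        assert np.isfinite(kl) and kl < 0.5

    def test_marginal_consistency_of_prior(self, k4_est):
        """Summing the assembled K=4 prior over the other tissues nearly
        reproduces each pairwise Probit table."""
        model = k4_est.model_
        for f in k4_est.pair_fits_:
            i, j = f.tissues
            marg = ht.marginalize_model(model, [i, j])
            pp = ht.probit_invert_pair(f.p, (i, j))
            # rebuild the 2x2 table from the pair's own Probit parameters
            Om = np.array([[1, pp.omega], [pp.omega, 1]])
            p11 = ht.bvn_upper_orthant(pp.tau1, pp.tau2, pp.omega)
            p01 = norm.sf(pp.tau2) - p11
            p10 = norm.sf(pp.tau1) - p11
            table = {(0, 0): 1 - p01 - p10 - p11, (0, 1): p01,
                     (1, 0): p10, (1, 1): p11}
            tv = 0.5 * sum(abs(marg.prob_of(k) - v)
                           for k, v in table.items())
            assert tv < 0.02

    def test_matrix_outputs_are_valid(self, k4_est):
        from hteqtl.model import check_correlation, check_psd
        check_correlation(k4_est.delta_)
        check_correlation(k4_est.omega_)
        check_psd(k4_est.sigma_)
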