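"""lfdr computation, adaptive FDR, marginalization, model summaries."""

import numpy as np
import pytest
from scipy.stats import norm

import hteqtl as ht
from hteqtl.model import HTModel


@pytest.fixture
def k1_model():
    return HTModel(1, [[0], [1]], [0.9, 0.1], [[1.0]], [[4.0]])


class TestLfdr:
    def test_k1_closed_form(self, k1_model):
        """Direct density-evaluation oracle for a scalar mixture."""
        eta = ht.lfdr(np.array([[3.0]]), k1_model, ht.ConfigSet("any", 1))
        num = 0.9 * norm.pdf(3, scale=1.0)
        den = num + 0.1 * norm.pdf(3, scale=np.sqrt(5.0))
        assert eta[0] == pytest.approx(num / den, abs=1e-12)
        assert eta[0] == pytest.approx(0.3548, abs=1e-4)

    def test_no_alternative_mass_gives_unit_lfdr(self):
        model = HTModel(2, [[0, 0]], [1.0], np.eye(2), np.eye(2) * 4)
        eta = ht.lfdr(np.array([[5.0, 5.0]]), model,
                      ht.ConfigSet("any", 2))
        assert eta[0] == 1.0

    def test_empty_null_gives_zero_lfdr(self, k1_model, rng):
        S = ht.ConfigSet("explicit", 1, configs=[(0,), (1,)])
        with pytest.warns(RuntimeWarning, match="no prior mass"):
            eta = ht.lfdr(rng.normal(size=(5, 1)), k1_model, S)
        assert np.all(eta == 0.0)

    def test_complementary_sets_sum_to_one(self, k9_model, k9_sim):
        _, zmat = k9_sim
        Z = zmat.Z[:200]
        S = ht.ConfigSet("any", 9)
        Sc = ht.ConfigSet("explicit", 9, configs=[tuple([0] * 9)])
        eta = ht.lfdr(Z, k9_model, S)
        eta_c = ht.lfdr(Z, k9_model, Sc)
        assert np.allclose(eta + eta_c, 1.0, atol=1e-12)

    def test_monotone_in_abs_z_for_k1(self, k1_model):
        z = np.linspace(0, 8, 40)[:, None]
        eta = ht.lfdr(z, k1_model, ht.ConfigSet("any", 1))
        assert np.all(np.diff(eta) < 0)

    def test_incomplete_rows_rejected(self, k1_model):
        with pytest.raises(ValueError, match="complete"):
            ht.lfdr(np.array([[np.nan]]), k1_model, ht.ConfigSet("any", 1))


class TestAdaptiveFdr:
    def test_worked_example(self):
        res = ht.adaptive_fdr(np.array([0.01, 0.04, 0.10, 0.20]), 0.05)
        assert res.n_reject == 2
        assert list(res.reject) == [True, True, False, False]

    def test_no_rejection_when_all_above_alpha(self):
        res = ht.adaptive_fdr(np.array([0.06, 0.5, 0.9]), 0.05)
        assert res.n_reject == 0

    def test_matches_bruteforce_prefix_scan(self, rng):
        lfdrs = rng.uniform(size=1000) ** 2
        alpha = 0.05
        res = ht.adaptive_fdr(lfdrs, alpha)
        s = np.sort(lfdrs)
        best = 0
        for n in range(1, 1001):
            if s[:n].mean() < alpha:
                best = n
        assert res.n_reject == best

    def test_rejected_mean_below_alpha(self, rng):
        for seed in range(5):
            lf = np.random.default_rng(seed).uniform(size=400) ** 3
            res = ht.adaptive_fdr(lf, 0.1)
            if res.n_reject:
                assert res.mean_lfdr_rejected < 0.1

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            ht.adaptive_fdr(np.array([0.1]), 1.5)


class TestMarginalize:
    def test_full_subset_is_identity(self, k9_model):
        m = ht.marginalize_model(k9_model, list(range(9)))
        assert np.allclose(m.probs, k9_model.probs)
        assert np.array_equal(m.configs, k9_model.configs)
        assert np.allclose(m.Delta, k9_model.Delta)

    def test_k3_exhaustive_summation(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(8))
        configs = [(a, b, c) for a in (0, 1) for b in (0, 1)
                   for c in (0, 1)]
        D = np.eye(3)
        model = HTModel(3, configs, probs, D, np.eye(3) * 2)
        m = ht.marginalize_model(model, [0, 1])
        for u in (0, 1):
            for v in (0, 1):
                expect = sum(p for c, p in zip(configs, probs)
                             if c[:2] == (u, v))
                assert m.prob_of((u, v)) == pytest.approx(expect, abs=1e-12)

    def test_marginal_compatibility_of_lfdr(self, k4_model, k4_sim):
        """lfdr under the marginalized model equals lfdr under the
        directly-restricted model on the restricted z-columns."""
        _, zmat = k4_sim
        Z = zmat.Z[:2000]
        for sub in ([0, 1], [1, 3], [0, 2]):
            marg = ht.marginalize_model(k4_model, sub)
            # independent restriction: build the 2-tissue model by hand
            ix = np.ix_(sub, sub)
            grouped = {}
            for c, p in zip(k4_model.configs, k4_model.probs):
                key = tuple(int(c[t]) for t in sub)
                grouped[key] = grouped.get(key, 0.0) + float(p)
            direct = HTModel(2, sorted(grouped),
                             [grouped[k] for k in sorted(grouped)],
                             k4_model.Delta[ix], k4_model.Sigma[ix])
            S = ht.ConfigSet("any", 2)
            a = ht.lfdr(Z[:, sub], marg, S)
            b = ht.lfdr(Z[:, sub], direct, S)
            assert np.allclose(a, b, atol=1e-12)


class TestSummaries:
    def test_hamming_two_point_prior(self):
        model = HTModel(3, [[0, 0, 0], [1, 1, 1]], [0.95, 0.05],
                        np.eye(3), np.eye(3))
        masses = ht.hamming_class_summary(model)
        assert np.allclose(masses, [0.95, 0, 0, 0.05])

    def test_hamming_uniform_prior_binomial(self):
        configs = [(a, b, c) for a in (0, 1) for b in (0, 1)
                   for c in (0, 1)]
        masses = ht.hamming_class_summary((configs, np.full(8, 0.125)))
        assert np.allclose(masses, np.array([1, 3, 3, 1]) / 8)

    def test_hamming_matches_popcount_oracle(self, rng):
        K = 6
        M = 20
        seen = set()
        configs = []
        while len(configs) < M:
            c = tuple(rng.integers(0, 2, K).tolist())
            if c not in seen:
                seen.add(c)
                configs.append(c)
        probs = rng.dirichlet(np.ones(M))
        masses = ht.hamming_class_summary((configs, probs))
        for m in range(K + 1):
            expect = sum(p for c, p in zip(configs, probs)
                         if sum(c) == m)
            assert masses[m] == pytest.approx(expect, abs=1e-12)


class TestClustering:
    def test_identical_tissues_merge_first_at_zero(self):
        S = np.array([[2.0, 2.0, 0.2], [2.0, 2.0, 0.2], [0.2, 0.2, 1.0]])
        link = ht.tissue_clustering(S)
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_strongest_correlation_merges_first(self):
        corr = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1],
                         [0.1, 0.1, 1.0]])
        link = ht.tissue_clustering(corr)
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[0, 2] == pytest.approx(0.1)

    def test_heights_match_bruteforce_single_linkage(self, rng):
        A = rng.standard_normal((6, 6))
        S = A @ A.T + 6 * np.eye(6)
        link = ht.tissue_clustering(S)
        # brute force: repeatedly merge the closest clusters (min over
        # cross-pairs)
        d = np.diag(S)
        dist = 1 - S / np.sqrt(np.outer(d, d))
        clusters = [{i} for i in range(6)]
        heights = []
        while len(clusters) > 1:
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    h = min(dist[i, j] for i in clusters[a]
                            for j in clusters[b])
                    if best is None or h < best[0]:
                        best = (h, a, b)
            h, a, b = best
            heights.append(h)
            clusters[a] |= clusters[b]
            del clusters[b]
        assert np.allclose(link[:, 2], heights, atol=1e-12)

    def test_newick_export(self):
        S = np.array([[2.0, 1.8, 0.2], [1.8, 2.0, 0.2], [0.2, 0.2, 1.0]])
        nwk = ht.linkage_to_newick(ht.tissue_clustering(S),
                                   ["a", "b", "c"])
        assert nwk.endswith(";") and "a" in nwk and "(" in nwk

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            ht.tissue_clustering(np.array([[0.0, 0], [0, 1.0]]))
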