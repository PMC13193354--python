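import numpy as np
import pytest

from hierpop import (AdmixtureModel, MixtureClustering, fit_admixture, fit_mixture,
                     panmixia_test, run_k_scan, select_k)
from hierpop._encode import encode
from hierpop._kernels import hard_loglik
from hierpop.admixture import AdmixtureFit, align_clusters

from conftest import make_gm, random_gm


class TestMixture:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        gm = random_gm(rng, n=10, L=3, n_alleles=4, missing=0.1)
        fit = fit_mixture(gm, 1)
        enc = encode(gm)
        beta = 0.5
        ll = 0.0
        for l in range(3):
            col = enc.calls[:, l, :].ravel()
            col = col[col >= 0]
            cnt = np.bincount(col, minlength=enc.n_alleles[l]).astype(float)
            phat = (cnt + beta) / (cnt.sum() + enc.n_alleles[l] * beta)
            ll += float((cnt * np.log(phat)).sum())
        assert fit.loglik == pytest.approx(ll)
        assert np.all(fit.Q == [[1.0]] * 10)

    def test_perfect_split_of_fixed_groups(self, two_fixed_groups):
        fit = fit_mixture(two_fixed_groups, 2, seed=1)
        z = fit.labels
        assert len(set(z[:20])) == 1 and len(set(z[20:])) == 1 and z[0] != z[-1]
        # with beta -> 0 the profiled log-likelihood approaches 0 at fixation
        tiny = fit_mixture(two_fixed_groups, 2, seed=1, beta=1e-9)
        assert abs(tiny.loglik) < 1e-3

    def test_seed_determinism_and_quality(self):
        rng = np.random.default_rng(1)
        gm = random_gm(rng, n=30, L=6, n_alleles=5, missing=0.1)
        f1 = fit_mixture(gm, 3, seed=9)
        f2 = fit_mixture(gm, 3, seed=9)
        assert np.array_equal(f1.labels, f2.labels) and f1.loglik == f2.loglik
        # annealed solution beats random assignments
        enc = encode(gm)
        rand_lls = [
            float(hard_loglik(enc.calls, enc.n_alleles,
                              rng.integers(0, 3, size=30), 3, 0.5))
            for _ in range(100)
        ]
        assert f1.loglik >= max(rand_lls) - 1e-9

    def test_label_permutation_leaves_loglik_unchanged(self):
        rng = np.random.default_rng(2)
        gm = random_gm(rng, n=20, L=4, n_alleles=4)
        enc = encode(gm)
        z = rng.integers(0, 3, size=20)
        perm = np.array([2, 0, 1])
        l0 = hard_loglik(enc.calls, enc.n_alleles, z, 3, 0.5)
        l1 = hard_loglik(enc.calls, enc.n_alleles, perm[z], 3, 0.5)
        assert l0 == pytest.approx(l1)

    def test_k_larger_than_n_rejected(self):
        gm = make_gm([[(1, 2)], [(1, 1)]])
        with pytest.raises(ValueError, match="exceeds"):
            fit_mixture(gm, 3)


class TestAdmixtureEM:
    def test_single_genotype_closed_form(self):
        # one individual (A,A), K=1, p_A fixed at 0.25 -> logL = 2 ln 0.25
        gm = make_gm([[(1, 1)], [(2, 2)]])  # second row defines the allele universe
        enc = encode(gm).subset([0])
        est = AdmixtureModel(n_clusters=1, max_iter=1, tol=1e-9)
        est.fit(enc, Q0=np.array([[1.0]]), P0=np.array([[0.25, 0.75]]))
        assert est.loglik_path_[0] == pytest.approx(2 * np.log(0.25))

    def test_fixed_groups_converge_to_one_hot(self, two_fixed_groups):
        fit = fit_admixture(two_fixed_groups, 2, seed=3, tol=1e-8)
        qmax = fit.Q.max(axis=1)
        assert np.all(qmax > 1 - 1e-3)
        assert len(set(fit.labels[:20])) == 1 and fit.labels[0] != fit.labels[-1]

    def test_em_monotone_and_simplex_invariants(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            gm = random_gm(rng, n=int(rng.integers(8, 20)), L=4,
                           n_alleles=int(rng.integers(2, 6)), missing=0.15)
            K = int(rng.integers(1, 4))
            fit = fit_admixture(gm, K, seed=int(rng.integers(2**31)),
                                init="random", tol=1e-8)
            assert np.all(np.diff(fit.loglik_path) >= -1e-8)
            assert np.allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)
            enc = encode(gm)
            sums = np.add.reduceat(fit.P, enc.offsets[:-1], axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)
            assert fit.loglik <= 1e-9

    def test_sklearn_params_round_trip(self):
        est = AdmixtureModel(n_clusters=4, tol=1e-7)
        params = est.get_params()
        assert params["n_clusters"] == 4
        est.set_params(n_clusters=2)
        assert est.n_clusters == 2


class TestSelectK:
    @staticmethod
    def _dummy_fits(loglik_by_k, R=2):
        out = {}
        for k, ll in loglik_by_k.items():
            out[k] = [AdmixtureFit("admixture", k, np.ones((1, k)) / k,
                                   np.ones((k, 2)) / 2, ll, 0, 1, True,
                                   np.zeros(1, int)) for _ in range(R)]
        return out

    def test_curvature_arithmetic(self):
        fits = self._dummy_fits({1: -1000.0, 2: -900.0, 3: -890.0, 4: -885.0})
        res = select_k(fits)
        tab = res.table.set_index("K")
        assert tab.loc[2, "D2"] == pytest.approx(90.0)
        assert tab.loc[3, "D2"] == pytest.approx(5.0)
        assert res.chosen_k == 2

    def test_linear_likelihood_flags_no_curvature(self):
        fits = self._dummy_fits({k: -1000.0 + 10.0 * k for k in range(1, 6)})
        res = select_k(fits)
        assert res.flag == "no-curvature" and res.chosen_k == 1

    def test_needs_contiguous_levels(self):
        fits = self._dummy_fits({1: -10.0, 3: -8.0, 4: -7.0})
        with pytest.raises(ValueError):
            select_k(fits)

    def test_two_deme_recovery_single_dataset(self, two_deme_dataset):
        gm, truth = two_deme_dataset
        fits = run_k_scan(gm, range(1, 6), n_replicates=10, seed=1)
        res = select_k(fits, gm=gm)
        assert res.chosen_k == 2
        best = max(fits[2], key=lambda f: f.loglik)
        from hierpop import compare_partitions
        ari, acc = compare_partitions(best.labels, truth.leaf_labels())
        assert acc >= 0.95


class TestPanmixia:
    def test_fixed_groups_minimal_p(self, two_fixed_groups):
        delta, p = panmixia_test(two_fixed_groups, R=2, B=19, seed=0)
        assert p == pytest.approx(1 / 20)
        assert delta > 0

    def test_identical_genotypes_accept_panmixia(self):
        gm = make_gm([[(1, 2), (1, 1)]] * 12)
        delta, p = panmixia_test(gm, R=2, B=19, seed=1)
        assert abs(delta) < 1e-6
        assert p > 0.5

    def test_size_control_under_true_panmixia(self):
        """simulated K=1 data should rarely reject at alpha = 0.05."""
        from hierpop import SimConfig, simulate_hierarchy

        rejections = 0
        for seed in range(20):
            gm, _ = simulate_hierarchy(
                SimConfig(depth=0, F_levels=(), n_loci=8,
                          alleles_per_locus=(8, 8), n_per_leaf=40, seed=seed))
            _, p = panmixia_test(gm, R=2, B=39, seed=seed)
            rejections += p < 0.05
        assert rejections <= 4  # binomial(20, 0.05): P(>4) < 0.003

    def test_contracts(self):
        gm = make_gm([[(1, 2)]] * 5)
        with pytest.raises(ValueError, match="n >= 10"):
            panmixia_test(gm)
        gm2 = make_gm([[(1, 2)]] * 12)
        with pytest.raises(ValueError, match="B must"):
            panmixia_test(gm2, B=5)


def test_align_clusters_recovers_permutation():
    rng = np.random.default_rng(5)
    Q_ref = rng.dirichlet(np.ones(3), size=50)
    Q = Q_ref[:, np.array([2, 0, 1])]
    cols = align_clusters(Q_ref, Q)
    assert np.array_equal(Q[:, cols], Q_ref)
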