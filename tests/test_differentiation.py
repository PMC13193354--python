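import numpy as np
import pytest

from hierpop import (SimConfig, amova, differentiation_stats, distance_matrix,
                     genotype_distance, simulate_hierarchy)

from conftest import make_gm, random_gm


class TestJostAndHedrick:
    def test_complete_differentiation(self, two_fixed_groups):
        recs = differentiation_stats(two_fixed_groups, mode="plugin", n_perm=99, n_boot=9)
        assert recs["D"].value == pytest.approx(1.0)
        assert recs["G''ST"].value == pytest.approx(1.0)
        assert recs["D"].perm_p == pytest.approx(0.01)

    def test_identical_frequencies_give_zero(self):
        geno = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)], [(1, 1)], [(2, 2)]]
        gm = make_gm(geno, groups=["a"] * 3 + ["b"] * 3)
        recs = differentiation_stats(gm, mode="plugin", n_perm=0, n_boot=2)
        assert recs["D"].value == pytest.approx(0.0, abs=1e-12)
        assert recs["G''ST"].value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_group_case(self):
        # p = (0.8, 0.2) vs (0.2, 0.8): H_S = 0.32, H_T = 0.5
        geno = ([[(1, 1)]] * 4 + [[(2, 2)]]) * 1 + ([[(2, 2)]] * 4 + [[(1, 1)]])
        gm = make_gm(geno, groups=["a"] * 5 + ["b"] * 5)
        recs = differentiation_stats(gm, mode="plugin", n_perm=0, n_boot=2)
        assert recs["D"].H_S == pytest.approx(0.32)
        assert recs["D"].H_T == pytest.approx(0.5)
        assert recs["D"].value == pytest.approx(2 * 0.18 / 0.68)
        assert recs["G''ST"].value == pytest.approx(2 * 0.18 / ((2 * 0.5 - 0.32) * 0.68))

    def test_invariance_to_relabeling_and_group_order(self):
        rng = np.random.default_rng(5)
        gm = random_gm(rng, n=24, L=5, n_alleles=6, missing=0.1, groups=2)
        base = differentiation_stats(gm, n_perm=0, n_boot=2, seed=1)
        # relabel alleles by an arbitrary injective map
        calls = gm.calls.copy()
        calls[calls > 0] = calls[calls > 0] * 7 + 3
        gm_relab = make_gm([[tuple(calls[i, l]) if calls[i, l, 0] > 0 else None
                             for l in range(5)] for i in range(24)],
                           groups=list(gm.group_labels))
        rel = differentiation_stats(gm_relab, n_perm=0, n_boot=2, seed=1)
        # reverse individual (and hence group) order
        rev = differentiation_stats(gm.subset(np.arange(23, -1, -1)),
                                    n_perm=0, n_boot=2, seed=1)
        for key in ("D", "G''ST"):
            assert rel[key].value == pytest.approx(base[key].value)
            assert rev[key].value == pytest.approx(base[key].value)

    def test_jackknife_se_positive_when_loci_differ(self):
        rng = np.random.default_rng(6)
        gm = random_gm(rng, n=30, L=6, n_alleles=8, groups=2)
        recs = differentiation_stats(gm, n_perm=0, n_boot=99, seed=2)
        per_locus = recs["D"].per_locus
        if np.ptp(per_locus[np.isfinite(per_locus)]) > 1e-9:
            assert recs["D"].jackknife_se > 0
        assert recs["D"].ci_low <= recs["D"].ci_high

    def test_monotone_in_generating_drift(self):
        means = []
        for F in (0.02, 0.05, 0.10, 0.20):
            vals = []
            for seed in range(30):
                cfg = SimConfig(depth=1, F_levels=(F,), n_loci=8,
                                alleles_per_locus=(8, 8), n_per_leaf=50, seed=seed)
                gm, _ = simulate_hierarchy(cfg)
                r = differentiation_stats(gm, mode="plugin", n_perm=0, n_boot=2)
                vals.append((r["D"].H_T - r["D"].H_S) / r["D"].H_T)
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)


class TestGenotypeDistance:
    @pytest.mark.parametrize(
        "a, b, d",
        [((1, 2), (1, 2), 0), ((1, 1), (1, 1), 0), ((1, 1), (2, 2), 4),
         ((1, 1), (2, 3), 3), ((1, 2), (3, 4), 2), ((1, 1), (1, 2), 1),
         ((1, 2), (1, 3), 1)],
    )
    def test_codominant_distance_table(self, a, b, d):
        assert genotype_distance(a, b) == d

    def test_matrix_rescales_for_missing_loci(self):
        # pair shares 1 of 2 loci: d2 = (2/1) * d2(locus0)
        gm = make_gm([[(1, 1), (1, 2)], [(2, 2), None]])
        D = distance_matrix(gm)
        assert D[0, 1] == pytest.approx(2 * 4.0)

    def test_zero_common_loci_raises_naming_pair(self):
        gm = make_gm([[(1, 1), None], [None, (2, 2)]])
        with pytest.raises(ValueError, match="i0.*i1"):
            distance_matrix(gm)


class TestAmova:
    def test_fixed_groups_phi_one(self):
        gm = make_gm([[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]],
                     groups=["a", "a", "b", "b"])
        res = amova(gm, n_perm=99)
        assert res.ss_among == pytest.approx(4.0)
        assert res.ss_within == pytest.approx(0.0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.percent_among + res.percent_within == pytest.approx(100.0)

    def test_identical_individuals(self):
        gm = make_gm([[(1, 2)]] * 6, groups=["a"] * 3 + ["b"] * 3)
        res = amova(gm, n_perm=99)
        assert res.phi_st == 0.0
        assert res.perm_p == 1.0

    def test_matches_brute_force_variance_components(self):
        """phi_ST equals direct group-mean algebra on allele-count vectors."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(6, 13))
            gm = random_gm(rng, n=n, L=3, n_alleles=4, missing=0.0, groups=2)
            res = amova(gm, n_perm=0)
            # brute force: x_i = concatenated allele-count vectors; ANOVA on x
            from hierpop._encode import encode
            enc = encode(gm)
            X = np.zeros((n, enc.total_alleles))
            for i in range(n):
                for l in range(3):
                    for s in (0, 1):
                        X[i, enc.offsets[l] + enc.calls[i, l, s]] += 1
            labels = gm.group_labels
            xbar = X.mean(axis=0)
            ss_total = 0.5 * ((X - xbar) ** 2).sum()
            ss_within = 0.0
            sizes = []
            for g in dict.fromkeys(labels):
                sub = X[labels == g]
                sizes.append(len(sub))
                ss_within += 0.5 * ((sub - sub.mean(axis=0)) ** 2).sum()
            P, N = len(sizes), n
            ms_a = (ss_total - ss_within) / (P - 1)
            ms_w = ss_within / (N - P)
            n0 = (N - sum(s**2 for s in sizes) / N) / (P - 1)
            s2a = (ms_a - ms_w) / n0
            phi = s2a / (s2a + ms_w) if (s2a + ms_w) > 0 else 0.0
            assert res.phi_st == pytest.approx(phi, abs=1e-10)

    def test_null_calibration_on_panmictic_data(self):
        rng = np.random.default_rng(8)
        ps = []
        for seed in range(60):
            gm, _ = simulate_hierarchy(
                SimConfig(depth=0, F_levels=(), n_loci=6, n_per_leaf=24, seed=seed))
            labels = np.asarray(["a"] * 12 + ["b"] * 12, dtype=object)
            ps.append(amova(gm.with_groups(labels), n_perm=99,
                            seed=int(rng.integers(2**31))).perm_p)
        # permutation p should not pile up at small values under the null
        assert (np.asarray(ps) <= 0.05).mean() < 0.15
        assert np.mean(ps) > 0.3

    def test_group_size_contract(self):
        gm = make_gm([[(1, 1)], [(1, 2)], [(2, 2)]], groups=["a", "a", "b"])
        with pytest.raises(ValueError, match=">= 2"):
            amova(gm)
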