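import numpy as np
import pytest
from scipy.stats import kstest

from hierpop import holm_adjust, hwe_test, hwe_table, ld_test
from hierpop.equilibrium import enumerate_hwe_arrays, _mc_log_probs

from conftest import make_gm


class TestHweExact:
    def test_two_heterozygotes_enumeration(self):
        # arrays for counts A:2,B:2 -> {AB,AB} P=2/3, {AA,BB} P=1/3
        assert hwe_test([(1, 2), (1, 2)]).p == pytest.approx(1.0)
        assert hwe_test([(1, 1), (2, 2)]).p == pytest.approx(1 / 3)

    def test_monomorphic_flag(self):
        res = hwe_test([(1, 1), (1, 1)])
        assert res.p == 1.0 and res.flag == "monomorphic"

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            hwe_test([(1, 2)])
        with pytest.raises(ValueError):
            hwe_test([(1, 2), (1, 2)], B=50)

    @pytest.mark.parametrize("counts", [(2, 2), (4, 2), (3, 3, 2), (5, 4, 3), (6, 6)])
    def test_enumeration_probabilities_sum_to_one(self, counts):
        logs = enumerate_hwe_arrays(np.array(counts))
        assert np.exp(logs).sum() == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_agrees_with_enumeration(self):
        # one moderate configuration; the full small-n grid runs in acceptance
        rng = np.random.default_rng(0)
        counts = np.array([4, 3, 3])
        logs_enum = enumerate_hwe_arrays(counts)
        probs = np.exp(logs_enum)
        mc = _mc_log_probs(counts, 20_000, rng)
        for cut in np.quantile(logs_enum, [0.25, 0.5, 0.75]):
            exact = probs[logs_enum <= cut + 1e-9].sum()
            est = (mc <= cut + 1e-9).mean()
            assert abs(exact - est) < 0.02

    def test_mc_path_used_above_cap(self):
        rng = np.random.default_rng(1)
        pairs = rng.integers(1, 11, size=(50, 2))
        res = hwe_test(pairs, B=2000, seed=3, enum_cap=100)
        assert res.method == "monte-carlo" and 0 < res.p <= 1

    def test_table_over_groups_and_loci(self):
        gm = make_gm(
            [[(1, 2), (1, 1)], [(1, 2), (1, 2)], [(2, 2), (2, 2)], [(1, 1), (1, 2)]],
            groups=["a", "a", "b", "b"],
        )
        df = hwe_table(gm, B=200)
        assert set(df.columns) >= {"group", "locus", "p", "significant"}
        assert len(df) == 4  # every group x locus cell has >= 2 genotyped individuals
        assert ((df["p"] > 0) & (df["p"] <= 1)).all()


class TestLd:
    def test_perfect_association_gives_minimal_p(self):
        rng = np.random.default_rng(2)
        a = rng.integers(1, 4, size=(40, 2)).astype(np.int32)
        calls = np.stack([a, a + 10], axis=1)  # locus2 relabels locus1 genotypes
        gm = make_gm([[tuple(calls[i, 0]), tuple(calls[i, 1])] for i in range(40)])
        B = 199
        res = ld_test(gm, "g", (0, 1), B=B, seed=5)
        assert res.p == pytest.approx(1 / (B + 1))

    def test_monomorphic_locus_skipped(self):
        gm = make_gm([[(1, 1), (1, 2)], [(1, 1), (2, 2)], [(1, 1), (1, 1)]])
        res = ld_test(gm, "g", (0, 1), B=199)
        assert res.method == "skipped"

    def test_null_pvalues_roughly_uniform(self):
        """Independently simulated HWE loci: permutation p approximately uniform.

        Three alleles per locus keep the genotype x genotype table well occupied
        at n = 50; very sparse tables make the (valid) test conservative instead.
        """
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(300):
            calls = np.sort(rng.integers(1, 4, size=(50, 2, 2)).astype(np.int32), axis=2)
            gm = make_gm([[tuple(calls[i, 0]), tuple(calls[i, 1])] for i in range(50)])
            ps.append(ld_test(gm, "g", (0, 1), B=199, seed=int(rng.integers(2**31))).p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestHolm:
    def test_stepdown_by_hand(self):
        df = holm_adjust([0.001, 0.02, 0.03], alpha=0.05)
        assert df["reject"].all()
        assert np.allclose(sorted(df["threshold"]), [0.05 / 3, 0.05 / 2, 0.05])

    def test_stops_at_first_failure(self):
        df = holm_adjust([0.001, 0.04, 0.049], alpha=0.05)
        # 0.04 > 0.05/2 -> accept it and everything larger
        assert df["reject"].tolist() == [True, False, False]

    def test_edge_cases(self):
        assert not holm_adjust([1.0, 1.0, 1.0])["reject"].any()
        assert holm_adjust([0.04], alpha=0.05)["reject"].all()
        with pytest.raises(ValueError):
            holm_adjust([])
        with pytest.raises(ValueError):
            holm_adjust([0.5], alpha=1.5)

    def test_rejections_monotone_in_alpha(self):
        rng = np.random.default_rng(4)
        p = rng.random(20)
        r1 = holm_adjust(p, alpha=0.01)["reject"]
        r2 = holm_adjust(p, alpha=0.10)["reject"]
        assert (r2 | ~r1).all()  # everything rejected at 0.01 also at 0.10


def test_wahlund_pooling_produces_detectable_heterozygote_deficits():
    """Pooling two drifted demes inflates homozygosity: the pooled sample shows
    F-hat > 0 and rejects HWE far above the 5% null rate, with every
    significant deviation on the deficit side."""
    from hierpop import SimConfig, simulate_hierarchy, diversity_table

    rng = np.random.default_rng(6)
    total_rej, total_deficit, n_loci = 0, 0, 0
    for seed in range(3):
        cfg = SimConfig(depth=1, F_levels=(0.15,), n_loci=15,
                        alleles_per_locus=(13, 31), n_per_leaf=40, seed=seed)
        gm, _ = simulate_hierarchy(cfg)
        pooled = gm.with_groups(["pool"] * 80)
        div = diversity_table(pooled)
        per_locus = div[div["locus"] != "over loci"]
        assert 1.0 - per_locus["H_O"].mean() / per_locus["H_E"].mean() > 0
        for l in range(15):
            res = hwe_test(pooled.calls[:, l, :], B=1000, seed=int(rng.integers(2**31)))
            n_loci += 1
            if res.p <= 0.05:
                total_rej += 1
                total_deficit += per_locus.iloc[l]["F"] > 0
    assert total_rej / n_loci > 0.3  # far above the 5% null rate
    assert total_deficit >= 0.9 * total_rej  # overwhelmingly on the deficit side
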