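import numpy as np
import pytest

from hierpop import (SimConfig, diversity_table, inject_missing, pool_locations,
                     simulate_hierarchy)
from hierpop.differentiation import differentiation_stats


def multilocus_f(gm, group=None):
    div = diversity_table(gm)
    over = div[div["locus"] == "over loci"]
    if group is not None:
        over = over[over["group"] == group]
    return float(1.0 - over["H_O"].mean() / over["H_E"].mean())


def test_same_seed_is_byte_identical():
    cfg = SimConfig(depth=2, F_levels=(0.1, 0.05), n_per_leaf=10, missing_rate=0.1, seed=5)
    gm1, t1 = simulate_hierarchy(cfg)
    gm2, t2 = simulate_hierarchy(cfg)
    assert gm1.equals(gm2)
    assert np.array_equal(t1.Q, t2.Q)
    assert all(np.allclose(a, b) for a, b in zip(t1.leaf_freqs, t2.leaf_freqs))


@pytest.mark.parametrize(
    "kw",
    [dict(depth=2, F_levels=(0.1,)), dict(F_levels=(0.1, 0.1, 1.5)),
     dict(missing_rate=1.0), dict(dirichlet_theta=0.0), dict(alleles_per_locus=(5, 3))],
)
def test_config_validation(kw):
    with pytest.raises(ValueError):
        simulate_hierarchy(SimConfig(**{**dict(seed=0), **kw}))


def test_truth_invariants_pure_mode():
    gm, truth = simulate_hierarchy(SimConfig(depth=2, F_levels=(0.1, 0.1), n_per_leaf=5, seed=1))
    assert truth.n_leaves == 4
    assert np.allclose(truth.Q.sum(axis=1), 1.0)
    assert np.all(np.isin(truth.Q, [0.0, 1.0]))  # one-hot in pure mode
    for lf in truth.leaf_freqs:
        assert np.allclose(lf.sum(axis=1), 1.0)


def test_admixed_mode_q_on_simplex():
    cfg = SimConfig(depth=1, F_levels=(0.15,), n_per_leaf=10, admix_alpha=0.5, seed=2)
    gm, truth = simulate_hierarchy(cfg)
    assert truth.leaf_of is None
    assert np.allclose(truth.Q.sum(axis=1), 1.0)
    assert (truth.Q > 0).all()


def test_depth_zero_is_panmictic():
    cfg = SimConfig(depth=0, F_levels=(), n_loci=15, n_per_leaf=200, seed=3)
    gm, _ = simulate_hierarchy(cfg)
    assert abs(multilocus_f(gm)) < 0.05


def test_tiny_drift_keeps_leaf_frequencies_near_ancestral():
    """F -> 0 limit: leaf frequency vectors stay ~0.02 (L1) from the ancestral
    vector at F = 0.001 for diallelic loci (L1 drift scales with allele count)."""
    cfg = SimConfig(depth=1, F_levels=(0.001,), n_loci=400,
                    alleles_per_locus=(2, 2), n_per_leaf=2, seed=4)
    _, truth = simulate_hierarchy(cfg)
    l1 = [np.abs(truth.leaf_freqs[l][j] - truth.ancestral_freqs[l]).sum()
          for l in range(400) for j in range(2)]
    assert np.mean(l1) < 0.025
    assert np.max(l1) < 0.2


def test_two_deme_gst_matches_monte_carlo_oracle():
    """Mean plug-in GST over replicate simulations matches the expectation of the
    Balding-Nichols draw computed directly on true frequencies (no genotypes)."""
    F = 0.10
    rng = np.random.default_rng(99)

    def oracle_rep():
        gst = []
        for _ in range(15):
            p = rng.dirichlet(np.ones(15))
            leaves = rng.dirichlet(np.maximum(p * (1 - F) / F, 1e-9), size=2)
            hs = np.mean(1 - (leaves**2).sum(axis=1))
            ht = 1 - ((leaves.mean(axis=0)) ** 2).sum()
            gst.append((hs, ht))
        hs, ht = np.mean(gst, axis=0)
        return (ht - hs) / ht

    oracle = np.mean([oracle_rep() for _ in range(300)])

    vals = []
    for seed in range(50):
        cfg = SimConfig(depth=1, F_levels=(F,), n_loci=15, alleles_per_locus=(15, 15),
                        n_per_leaf=500, seed=seed)
        gm, _ = simulate_hierarchy(cfg)
        recs = differentiation_stats(gm, mode="plugin", n_perm=0, n_boot=2, seed=seed)
        hs, ht = recs["D"].H_S, recs["D"].H_T
        vals.append((ht - hs) / ht)
    assert abs(np.mean(vals) - oracle) < 0.03


def test_nestedness_siblings_less_differentiated_than_cousins():
    sib, cous = [], []
    for seed in range(30):
        cfg = SimConfig(depth=2, F_levels=(0.05, 0.05), n_loci=10,
                        alleles_per_locus=(10, 10), n_per_leaf=30, seed=seed)
        gm, truth = simulate_hierarchy(cfg)
        labels = truth.leaf_labels()

        def gst(a, b):
            idx = np.flatnonzero((labels == a) | (labels == b))
            recs = differentiation_stats(gm.subset(idx), mode="plugin",
                                         n_perm=0, n_boot=2, seed=0)
            return (recs["D"].H_T - recs["D"].H_S) / recs["D"].H_T

        sib.append(gst("deme0", "deme1"))
        cous.append(gst("deme0", "deme2"))
    assert np.mean(sib) < np.mean(cous)


class TestPoolLocations:
    def test_single_leaf_mapping_relabels_without_touching_genotypes(self):
        gm, truth = simulate_hierarchy(SimConfig(depth=1, F_levels=(0.1,), n_per_leaf=5, seed=6))
        pooled = pool_locations(gm, truth, {"siteX": {"deme0": 1.0}}, seed=1)
        assert np.array_equal(pooled.calls, gm.calls)
        assert (pooled.group_labels[:5] == "siteX").all()
        assert (pooled.group_labels[5:] == "deme1").all()

    def test_unknown_leaf_and_bad_weights(self):
        gm, truth = simulate_hierarchy(SimConfig(depth=1, F_levels=(0.1,), n_per_leaf=5, seed=6))
        with pytest.raises(ValueError, match="unknown leaf"):
            pool_locations(gm, truth, {"x": {"nope": 1.0}})
        with pytest.raises(ValueError, match="sum to"):
            pool_locations(gm, truth, {"x": {"deme0": 0.7}})

    def test_pooling_same_leaf_twice_gives_no_substructure(self):
        gm, truth = simulate_hierarchy(
            SimConfig(depth=1, F_levels=(0.15,), n_loci=15, n_per_leaf=80, seed=8))
        sub = gm.subset(np.flatnonzero(truth.leaf_labels() == "deme0"))
        half = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
        assert abs(multilocus_f(sub.with_groups(["pool"] * 80))) < 0.06


class TestInjectMissing:
    def test_rate_zero_identity(self):
        gm, _ = simulate_hierarchy(SimConfig(depth=1, F_levels=(0.1,), n_per_leaf=5, seed=9))
        assert inject_missing(gm, 0.0) is gm

    def test_rate_near_typical_survey_average(self):
        gm, _ = simulate_hierarchy(
            SimConfig(depth=1, F_levels=(0.1,), n_loci=15, n_per_leaf=70, seed=10))
        out = inject_missing(gm, 0.186, seed=1)
        n_calls = out.n_individuals * out.n_loci
        frac = out.missing_mask.sum() / n_calls
        sd = np.sqrt(0.186 * (1 - 0.186) / n_calls)
        assert abs(frac - 0.186) < 3 * sd

    def test_rate_one_rejected(self):
        gm, _ = simulate_hierarchy(SimConfig(depth=1, F_levels=(0.1,), n_per_leaf=5, seed=9))
        with pytest.raises(ValueError):
            inject_missing(gm, 1.0)
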