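import numpy as np
import pytest

from hierpop import GenotypeMatrix, SimConfig, simulate_hierarchy


def make_gm(genotypes, groups=None, ids=None, loci=None):
    """Small GenotypeMatrix from a nested list [[ (a,b) | None, ... ] per individual]."""
    n = len(genotypes)
    L = len(genotypes[0])
    calls = np.full((n, L, 2), -1, dtype=np.int32)
    for i, row in enumerate(genotypes):
        for l, call in enumerate(row):
            if call is not None:
                calls[i, l] = call
    return GenotypeMatrix(
        ids or [f"i{k}" for k in range(n)],
        np.asarray(groups if groups is not None else ["g"] * n, dtype=object),
        loci or [f"L{k}" for k in range(L)],
        calls,
    )


@pytest.fixture
def two_fixed_groups():
    """Two groups of 20, every locus fixed for allele 1 in group 1 / 2 in group 2."""
    geno = [[(1, 1)] * 5] * 20 + [[(2, 2)] * 5] * 20
    return make_gm(geno, groups=["g1"] * 20 + ["g2"] * 20)


@pytest.fixture(scope="session")
def two_deme_dataset():
    """Simulated two-deme dataset (F = 0.10, n = 50 + 50, 15 loci, 15 alleles)."""
    cfg = SimConfig(depth=1, F_levels=(0.10,), n_loci=15, alleles_per_locus=(15, 15),
                    n_per_leaf=50, seed=7)
    return simulate_hierarchy(cfg)


def random_gm(rng, n=12, L=4, n_alleles=4, missing=0.1, groups=1):
    calls = rng.integers(1, n_alleles + 1, size=(n, L, 2)).astype(np.int32)
    drop = rng.random((n, L)) < missing
    calls[drop] = -1
    labels = np.asarray([f"g{k % groups}" for k in range(n)], dtype=object)
    return GenotypeMatrix([f"i{k}" for k in range(n)], labels,
                          [f"L{k}" for k in range(L)], calls)
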