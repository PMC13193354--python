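"""Internal numeric encoding of genotype matrices for the likelihood machinery.

Clustering and EM work on allele *indices* within each locus (0..A_l-1) rather
than raw allele labels.  ``EncodedGenotypes`` carries the index-coded call array,
per-locus allele universes and the flattened per-copy arrays the EM E/M steps use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_genotypes import MISSING, GenotypeMatrix


@dataclass
class EncodedGenotypes:
    calls: np.ndarray        # (n, L, 2) int32 allele index, -1 missing
    n_alleles: np.ndarray    # (L,) int64, observed allele count per locus
    offsets: np.ndarray      # (L+1,) cumulative column offsets
    allele_labels: list      # per locus, array of original labels (sorted)
    ids: list

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def total_alleles(self) -> int:
        return int(self.offsets[-1])

    def copy_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten non-missing gene copies to (ind, locus, global allele column)."""
        n, L, _ = self.calls.shape
        ind = np.repeat(np.arange(n), 2 * L)
        loc = np.tile(np.repeat(np.arange(L), 2), n)
        al = self.calls.reshape(-1)
        ok = al >= 0
        col = self.offsets[loc[ok]] + al[ok]
        return ind[ok], loc[ok], col

    def subset(self, indices) -> "EncodedGenotypes":
        idx = np.asarray(indices, dtype=int)
        return EncodedGenotypes(
            self.calls[idx].copy(),
            self.n_alleles,
            self.offsets,
            self.allele_labels,
            [self.ids[i] for i in idx],
        )


def encode(gm: GenotypeMatrix) -> EncodedGenotypes:
    """Map allele labels to dense per-locus indices (missing stays -1)."""
    n, L = gm.n_individuals, gm.n_loci
    calls = np.full((n, L, 2), -1, dtype=np.int32)
    labels = []
    n_alleles = np.zeros(L, dtype=np.int64)
    for l in range(L):
        alleles = gm.locus_alleles(l)
        if alleles.size == 0:
            alleles = np.array([0], dtype=np.int32)  # degenerate: all missing
        labels.append(alleles)
        n_alleles[l] = len(alleles)
        lut = {int(a): j for j, a in enumerate(alleles)}
        for s in (0, 1):
            col = gm.calls[:, l, s]
            for i in range(n):
                v = int(col[i])
                if v != MISSING:
                    calls[i, l, s] = lut[v]
    offsets = np.zeros(L + 1, dtype=np.int64)
    offsets[1:] = np.cumsum(n_alleles)
    return EncodedGenotypes(calls, n_alleles, offsets, labels, list(gm.individual_ids))


def as_encoded(X) -> EncodedGenotypes:
    if isinstance(X, EncodedGenotypes):
        return X
    if isinstance(X, GenotypeMatrix):
        return encode(X)
    raise TypeError(f"expected GenotypeMatrix or EncodedGenotypes, got {type(X).__name__}")
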