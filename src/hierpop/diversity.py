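"""Within-group diversity: heterozygosities, F, PIC, private alleles, richness.

Expected heterozygosity is the plug-in estimator H_E = 1 - sum(p^2); the unbiased
variant uH_E = 2N/(2N-1) * H_E is reported alongside.  The inbreeding coefficient
F = 1 - H_O/H_E is undefined (NaN) at monomorphic loci.  Polymorphic information
content follows the classic codominant-marker definition
PIC = 1 - sum(p^2) - sum_{a<b} 2 p_a^2 p_b^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_genotypes import AlleleCountTable, GenotypeMatrix, allele_counts

__all__ = [
    "locus_diversity",
    "diversity_table",
    "rarefied_richness",
    "jackknife_richness",
]


def _pic(freqs: np.ndarray) -> float:
    s2 = float(np.sum(freqs**2))
    cross = (s2**2 - float(np.sum(freqs**4))) / 2.0  # sum_{a<b} p_a^2 p_b^2
    return 1.0 - s2 - 2.0 * cross


def diversity_table(gm: GenotypeMatrix, grouping=None) -> pd.DataFrame:
    """Per (group, locus) diversity records plus per-group 'over loci' mean rows.

    Columns: group, locus, N (genotyped individuals), N_A, H_O, H_E, uH_E, F,
    PIC, n_private.  Group x locus cells with zero genotyped individuals are
    skipped.  Private alleles are those absent from every other group.
    """
    act = allele_counts(gm, grouping)
    labels = np.asarray(grouping, dtype=object) if grouping is not None else gm.group_labels
    miss = gm.missing_mask
    het = gm.calls[:, :, 0] != gm.calls[:, :, 1]

    rows = []
    G, L = len(act.group_names), len(act.locus_names)
    for g, gname in enumerate(act.group_names):
        in_g = labels == gname
        per_locus = []
        for l, lname in enumerate(act.locus_names):
            N = int(act.n_ind[g, l])
            if N == 0:
                continue
            freqs = np.array(list(act.frequencies(g, l).values()))
            alleles = set(act.counts[g][l])
            others = set()
            for g2 in range(G):
                if g2 != g:
                    others.update(act.counts[g2][l])
            h_e = 1.0 - float(np.sum(freqs**2))
            ok = in_g & ~miss[:, l]
            h_o = float(het[ok, l].mean()) if ok.any() else 0.0
            rec = {
                "group": gname,
                "locus": lname,
                "N": N,
                "N_A": len(alleles),
                "H_O": h_o,
                "H_E": h_e,
                "uH_E": h_e * 2 * N / (2 * N - 1) if N > 0 else np.nan,
                "F": 1.0 - h_o / h_e if h_e > 0 else np.nan,
                "PIC": _pic(freqs),
                "n_private": len(alleles - others),
            }
            per_locus.append(rec)
        rows.extend(per_locus)
        if per_locus:
            sub = pd.DataFrame(per_locus)
            rows.append(
                {
                    "group": gname,
                    "locus": "over loci",
                    "N": sub["N"].mean(),
                    "N_A": sub["N_A"].mean(),
                    "H_O": sub["H_O"].mean(),
                    "H_E": sub["H_E"].mean(),
                    "uH_E": sub["uH_E"].mean(),
                    "F": sub["F"].mean(skipna=True),
                    "PIC": sub["PIC"].mean(),
                    "n_private": sub["n_private"].sum(),
                }
            )
    return pd.DataFrame(rows)


# Alias: per (group, locus) records straight from a genotype matrix.
def locus_diversity(gm: GenotypeMatrix, grouping=None) -> pd.DataFrame:
    return diversity_table(gm, grouping)


def rarefied_richness(counts: dict[int, int] | AlleleCountTable, g: int,
                      group: int | None = None, locus: int | None = None) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies.

    Hypergeometric closed form: E[A_g] = sum_a [1 - C(N - N_a, g) / C(N, g)]
    with N total copies and N_a copies of allele a.
    """
    if isinstance(counts, AlleleCountTable):
        counts = counts.counts[group][locus]
    na = np.array(list(counts.values()), dtype=float)
    N = na.sum()
    if not (1 <= g <= N):
        raise ValueError(f"g must be in [1, {int(N)}]")
    # C(N - N_a, g) / C(N, g) via log-gammas; zero when N - N_a < g
    keep = (N - na) >= g
    ratio = np.zeros_like(na)
    if keep.any():
        m = N - na[keep]
        ratio[keep] = np.exp(
            gammaln(m + 1) - gammaln(g + 1) - gammaln(m - g + 1)
            - (gammaln(N + 1) - gammaln(g + 1) - gammaln(N - g + 1))
        )
    return float(np.sum(1.0 - ratio))


def jackknife_richness(gm: GenotypeMatrix, group, locus) -> tuple[float, float]:
    """First-order jackknife estimate of allelic richness over individuals.

    S_jack1 = S_obs + Q1 * (m - 1) / m, with m genotyped individuals and Q1 the
    number of alleles seen in exactly one individual; the variance is the
    Heltshe–Forrester estimator var = ((m-1)/m) * (sum_j j^2 f_j - Q1^2 / m),
    where f_j counts individuals carrying exactly j of the unique alleles.
    """
    l = gm.locus_names.index(locus) if isinstance(locus, str) else int(locus)
    in_g = gm.group_labels == group
    ok = in_g & ~gm.missing_mask[:, l]
    idx = np.flatnonzero(ok)
    m = idx.size
    if m < 2:
        raise ValueError("jackknife richness needs >= 2 genotyped individuals")
    carriers: dict[int, set[int]] = {}
    for i in idx:
        for a in gm.calls[i, l]:
            carriers.setdefault(int(a), set()).add(int(i))
    s_obs = len(carriers)
    unique_alleles = [a for a, who in carriers.items() if len(who) == 1]
    q1 = len(unique_alleles)
    s_jack = s_obs + q1 * (m - 1) / m
    # f_j: individuals carrying exactly j unique alleles
    per_ind = {int(i): 0 for i in idx}
    for a in unique_alleles:
        (i,) = carriers[a]
        per_ind[i] += 1
    js = np.array(list(per_ind.values()), dtype=float)
    var = (m - 1) / m * (float(np.sum(js**2)) - q1**2 / m)
    return float(s_jack), float(np.sqrt(max(var, 0.0)))
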