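"""Among-group differentiation: Jost's D, Hedrick's G''ST, genotype distances, AMOVA.

Heterozygosity components follow Nei & Chesser's small-sample corrections by
default (plug-in estimators are available for closed-form checks).  With K groups,
per-locus within/total heterozygosities H_S, H_T:

    D      = K/(K-1) * (H_T - H_S) / (1 - H_S)          (Jost)
    G''ST  = K (H_T - H_S) / ((K H_T - H_S)(1 - H_S))   (Hedrick, standardized)

Multi-locus values combine the across-locus means of H_S and H_T (standard
GST-family practice; stable when some loci are nearly monomorphic).  Uncertainty
is jackknife SE and percentile bootstrap CI over loci; significance is by
permutation of individual group labels.

Genotype distances are the squared codominant distances d2 = 1/2 * |c1 - c2|^2 on
allele-count vectors (0/1/2 entries), which generate the familiar table
AA-AA 0, AA-AB 1, AB-AC 1, AB-CD 2, AA-BC 3, AA-BB 4; the two-level AMOVA and its
phi-ST derive from these distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._encode import encode
from .io_genotypes import GenotypeMatrix

__all__ = [
    "DifferentiationRecord",
    "AmovaResult",
    "differentiation_stats",
    "pairwise_differentiation",
    "genotype_distance",
    "distance_matrix",
    "amova",
]


@dataclass
class DifferentiationRecord:
    statistic: str
    per_locus: np.ndarray
    loci: list[str]
    value: float
    jackknife_se: float
    ci_low: float
    ci_high: float
    perm_p: float
    K: int
    H_S: float
    H_T: float
    mode: str


@dataclass
class AmovaResult:
    phi_st: float
    sigma2_among: float
    sigma2_within: float
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    perm_p: float
    percent_among: float
    percent_within: float


# ---------------------------------------------------------------------------
# heterozygosity components
# ---------------------------------------------------------------------------

def _components(gm: GenotypeMatrix, gidx: np.ndarray, G: int, mode: str):
    """Per-locus (H_S, H_T, K_eff) under a group-index vector.

    Groups with zero genotyped individuals at a locus are excluded from that
    locus's means.  ``mode``: "nei-chesser" (default small-sample correction)
    or "plugin".
    """
    enc = encode(gm)
    L, total = enc.n_loci, enc.total_alleles
    cp_i, cp_l, cp_col = enc.copy_arrays()
    counts = np.zeros((G, total))
    np.add.at(counts, (gidx[cp_i], cp_col), 1.0)
    miss = gm.missing_mask
    het = (gm.calls[:, :, 0] != gm.calls[:, :, 1]) & ~miss
    n_gl = np.zeros((G, L))
    het_gl = np.zeros((G, L))
    np.add.at(n_gl, gidx, (~miss).astype(float))
    np.add.at(het_gl, gidx, het.astype(float))

    copies = 2.0 * n_gl  # (G, L)
    copies_rep = np.repeat(copies, enc.n_alleles, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(copies_rep > 0, counts / copies_rep, 0.0)
    sum_sq = np.add.reduceat(p**2, enc.offsets[:-1], axis=1)  # (G, L)

    present = n_gl > 0
    k_eff = present.sum(axis=0).astype(float)  # groups contributing per locus
    hs_plug = np.where(present, 1.0 - sum_sq, 0.0).sum(axis=0) / np.maximum(k_eff, 1)
    pbar = np.zeros((1, total))
    w = present.astype(float) / np.maximum(k_eff, 1.0)[None, :]
    pbar = (p * np.repeat(w, enc.n_alleles, axis=1)).sum(axis=0)
    ht_plug = 1.0 - np.add.reduceat(pbar**2, enc.offsets[:-1])

    if mode == "plugin":
        return hs_plug, ht_plug, k_eff

    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(present, 1.0 / np.maximum(n_gl, 1e-12), 0.0)
        n_harm = k_eff / inv.sum(axis=0)
        ho = np.where(present, het_gl / np.maximum(n_gl, 1e-12), 0.0).sum(axis=0) / np.maximum(k_eff, 1)
    safe = n_harm > 1
    hs = np.where(safe, n_harm / np.maximum(n_harm - 1, 1e-12) * (hs_plug - ho / (2 * np.maximum(n_harm, 1e-12))), hs_plug)
    ht = np.where(safe, ht_plug + hs / np.maximum(n_harm * k_eff, 1e-12) - ho / (2 * np.maximum(n_harm, 1e-12) * np.maximum(k_eff, 1)), ht_plug)
    return hs, ht, k_eff


def _jost_d(hs: float, ht: float, K: float) -> float:
    if 1.0 - hs <= 0 or K < 2:
        return np.nan
    return K / (K - 1.0) * (ht - hs) / (1.0 - hs)


def _g_dblprime(hs: float, ht: float, K: float) -> float:
    denom = (K * ht - hs) * (1.0 - hs)
    if denom <= 0 or K < 2:
        return 0.0 if ht == hs else np.nan
    return K * (ht - hs) / denom


def differentiation_stats(
    gm: GenotypeMatrix,
    grouping=None,
    n_perm: int = 999,
    n_boot: int = 999,
    seed: int = 0,
    mode: str = "nei-chesser",
) -> dict[str, DifferentiationRecord]:
    """Jost's D and Hedrick's G''ST with jackknife SE, bootstrap CI, permutation p.

    Loci where fewer than two groups have genotyped individuals are excluded.
    Permutations shuffle individual group labels and recompute the multi-locus
    statistics; the add-one estimator gives p.
    """
    labels = np.asarray(grouping, dtype=object) if grouping is not None else gm.group_labels
    names: list = []
    for g in labels:
        if g not in names:
            names.append(g)
    G = len(names)
    if G < 2:
        raise ValueError("need >= 2 groups")
    lut = {g: i for i, g in enumerate(names)}
    gidx = np.array([lut[g] for g in labels])

    hs, ht, k_eff = _components(gm, gidx, G, mode)
    include = k_eff >= 2
    if not include.any():
        raise ValueError("no locus has >= 2 groups with genotyped individuals")
    hs, ht = hs[include], ht[include]
    loci = [n for n, ok in zip(gm.locus_names, include) if ok]
    K = float(G)

    def multi(hs_v, ht_v):
        mhs, mht = float(np.mean(hs_v)), float(np.mean(ht_v))
        return _jost_d(mhs, mht, K), _g_dblprime(mhs, mht, K), mhs, mht

    d_loc = np.array([_jost_d(a, b, K) for a, b in zip(hs, ht)])
    g_loc = np.array([_g_dblprime(a, b, K) for a, b in zip(hs, ht)])
    d_obs, g_obs, mhs, mht = multi(hs, ht)

    Lx = hs.size
    # delete-one-locus jackknife (undefined with a single locus)
    if Lx >= 2:
        d_j = np.empty(Lx)
        g_j = np.empty(Lx)
        for l in range(Lx):
            keep = np.arange(Lx) != l
            d_j[l], g_j[l], _, _ = multi(hs[keep], ht[keep])
        se = lambda v: float(np.sqrt((Lx - 1) / Lx * np.sum((v - v.mean()) ** 2)))
    else:
        d_j = g_j = np.zeros(1)
        se = lambda v: 0.0

    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, Lx, size=(n_boot, Lx))
    boots = np.array([multi(hs[b], ht[b])[:2] for b in boot_idx])
    ci_d = np.percentile(boots[:, 0], [2.5, 97.5])
    ci_g = np.percentile(boots[:, 1], [2.5, 97.5])

    hits_d = hits_g = 0
    for _ in range(n_perm):
        perm = rng.permutation(gidx)
        hs_p, ht_p, _ = _components(gm, perm, G, mode)
        d_p, g_p, _, _ = multi(hs_p[include], ht_p[include])
        hits_d += d_p >= d_obs - 1e-12
        hits_g += g_p >= g_obs - 1e-12
    p_d = (1 + hits_d) / (1 + n_perm)
    p_g = (1 + hits_g) / (1 + n_perm)

    return {
        "D": DifferentiationRecord("D", d_loc, loci, d_obs, se(d_j), *ci_d, p_d, G, mhs, mht, mode),
        "G''ST": DifferentiationRecord("G''ST", g_loc, loci, g_obs, se(g_j), *ci_g, p_g, G, mhs, mht, mode),
    }


def pairwise_differentiation(gm: GenotypeMatrix, grouping=None, n_perm: int = 999,
                             n_boot: int = 99, seed: int = 0,
                             mode: str = "nei-chesser") -> pd.DataFrame:
    """Group-pair differentiation (the Jost's D / G''ST half-matrix layout as a
    tidy frame of pairs with permutation p-values)."""
    labels = np.asarray(grouping, dtype=object) if grouping is not None else gm.group_labels
    names = list(dict.fromkeys(labels))
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            mask = (labels == names[i]) | (labels == names[j])
            sub = gm.subset(np.flatnonzero(mask))
            recs = differentiation_stats(sub, grouping=labels[mask],
                                         n_perm=n_perm, n_boot=n_boot,
                                         seed=int(rng.integers(2**31 - 1)), mode=mode)
            hs, ht = recs["D"].H_S, recs["D"].H_T
            rows.append({
                "group1": names[i], "group2": names[j],
                "D": recs["D"].value, "D_p": recs["D"].perm_p,
                "G''ST": recs["G''ST"].value, "G''ST_p": recs["G''ST"].perm_p,
                "GST": (ht - hs) / ht if ht > 0 else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# codominant genotype distances
# ---------------------------------------------------------------------------

def genotype_distance(call1, call2) -> float:
    """Squared codominant distance between two single-locus calls.

    d2 = 1/2 * sum_a (c1_a - c2_a)^2 on allele-count vectors with entries 0/1/2.
    """
    alleles = sorted(set(call1) | set(call2))
    c1 = np.array([list(call1).count(a) for a in alleles], dtype=float)
    c2 = np.array([list(call2).count(a) for a in alleles], dtype=float)
    return float(0.5 * np.sum((c1 - c2) ** 2))


def distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Multi-locus squared-distance matrix with missing-locus rescaling.

    A pair's distance sums its per-locus d2 over commonly scored loci, rescaled by
    L / L_observed.  A pair with no commonly scored locus raises, naming the pair.
    """
    enc = encode(gm)
    n, L = enc.n_individuals, enc.n_loci
    dsum = np.zeros((n, n))
    lobs = np.zeros((n, n))
    for l in range(L):
        A = int(enc.n_alleles[l])
        X = np.zeros((n, A))
        obs = enc.calls[:, l, 0] >= 0
        rows = np.flatnonzero(obs)
        for s in (0, 1):
            np.add.at(X, (rows, enc.calls[rows, l, s]), 1.0)
        sq = (X**2).sum(axis=1)
        Dl = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * X @ X.T)
        mask = np.outer(obs, obs)
        dsum += np.where(mask, Dl, 0.0)
        lobs += mask
    off = ~np.eye(n, dtype=bool)
    if np.any(lobs[off] == 0):
        i, j = np.argwhere((lobs == 0) & off)[0]
        raise ValueError(
            f"individuals {gm.individual_ids[i]!r} and {gm.individual_ids[j]!r} "
            "share no scored locus"
        )
    out = np.zeros((n, n))
    out[off] = L / lobs[off] * dsum[off]
    np.fill_diagonal(out, 0.0)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# two-level AMOVA
# ---------------------------------------------------------------------------

def _ss_within(D: np.ndarray, gidx: np.ndarray, G: int) -> float:
    ss = 0.0
    for g in range(G):
        idx = np.flatnonzero(gidx == g)
        ss += D[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def amova(gm: GenotypeMatrix, grouping=None, n_perm: int = 999, seed: int = 0) -> AmovaResult:
    """Two-level AMOVA on squared codominant genotype distances.

    SS_total = (1/N) sum_{i<j} d2_ij; SS_within sums per-group pair distances
    scaled by group size; variance components come from the mean squares with
    n0 = (N - sum n_g^2 / N) / (P - 1).  phi_ST = s2_among / (s2_among + s2_within)
    is reported raw (the percent display floors it at zero); p is the proportion
    of group-label permutations with phi_ST at least the observed, add-one
    corrected.
    """
    labels = np.asarray(grouping, dtype=object) if grouping is not None else gm.group_labels
    names = list(dict.fromkeys(labels))
    G = len(names)
    if G < 2:
        raise ValueError("need >= 2 groups")
    lut = {g: i for i, g in enumerate(names)}
    gidx = np.array([lut[g] for g in labels])
    sizes = np.bincount(gidx, minlength=G)
    if np.any(sizes < 2):
        raise ValueError("every group must have >= 2 individuals")
    N = gidx.size
    if N <= G:
        raise ValueError("need more individuals than groups")

    D = distance_matrix(gm)
    ss_total = D.sum() / (2.0 * N)
    df_among, df_within = G - 1, N - G
    n0 = (N - float(np.sum(sizes**2)) / N) / df_among

    def phi(gvec: np.ndarray) -> tuple[float, float, float, float]:
        ssw = _ss_within(D, gvec, G)
        ssa = ss_total - ssw
        ms_a, ms_w = ssa / df_among, ssw / df_within
        s2w = ms_w
        s2a = (ms_a - ms_w) / n0
        tot = s2a + s2w
        return (s2a / tot if tot > 0 else 0.0), ssa, ssw, s2a

    phi_obs, ssa, ssw, s2a = phi(gidx)
    s2w = ssw / df_within
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += phi(rng.permutation(gidx))[0] >= phi_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    s2a_disp = max(s2a, 0.0)
    tot = s2a_disp + s2w
    pct_among = 100.0 * s2a_disp / tot if tot > 0 else 0.0
    return AmovaResult(
        phi_st=float(phi_obs),
        sigma2_among=float(s2a),
        sigma2_within=float(s2w),
        df_among=df_among,
        df_within=df_within,
        ss_among=float(ssa),
        ss_within=float(ssw),
        perm_p=float(p),
        percent_among=pct_among,
        percent_within=100.0 - pct_among,
    )
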