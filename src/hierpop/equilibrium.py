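"""Exact tests for Hardy–Weinberg equilibrium and genotypic linkage disequilibrium.

The HWE test is the conditional probability ("exact") test: given the allele
counts at a locus, the probability of a genotype array under random mating is

    P(array) = n! / prod_{a<=b} n_ab!  *  prod_a n_a! / (2n)!  *  2^h

with h the number of heterozygotes.  The p-value is Pr[P <= P_observed] under
that conditional null.  Small array spaces are enumerated exhaustively; larger
ones are sampled by random pairings of the 2n gene copies, which draws exactly
from the conditional null, with the add-one estimator p = (1 + hits) / (1 + B).

The LD test is a genotypic G-test: the log-likelihood-ratio statistic of the
genotype x genotype contingency table for a locus pair, with significance from
permuting one locus's genotype column across individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .io_genotypes import GenotypeMatrix

__all__ = [
    "TestResult",
    "hwe_test",
    "hwe_table",
    "ld_test",
    "ld_table",
    "holm_adjust",
    "enumerate_hwe_arrays",
]

_LOG2 = np.log(2.0)
_ENUM_CAP = 100_000


@dataclass
class TestResult:
    statistic: float
    p: float
    B: int
    method: str  # "enumeration" | "monte-carlo" | "permutation" | "skipped"
    flag: str = ""
    significant: bool | None = None


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _compact(pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel allele values to 0..A-1; return (pairs, copy counts per allele)."""
    pairs = np.asarray(pairs, dtype=np.int64)
    alleles, flat = np.unique(pairs, return_inverse=True)
    pairs = flat.reshape(pairs.shape)
    counts = np.bincount(pairs.ravel(), minlength=alleles.size)
    return pairs, counts


def _log_p_array(geno_counts: dict[tuple[int, int], int], allele_counts: np.ndarray) -> float:
    n = sum(geno_counts.values())
    h = sum(c for (a, b), c in geno_counts.items() if a != b)
    out = gammaln(n + 1) - sum(gammaln(c + 1) for c in geno_counts.values())
    out += float(np.sum(gammaln(allele_counts + 1))) - gammaln(2 * n + 1)
    out += h * _LOG2
    return float(out)


def _space_bound(n: int, A: int) -> float:
    """Stars-and-bars overcount of the genotype-array space: the number of ways to
    put n individuals into the A(A+1)/2 genotype classes, ignoring the allele-count
    constraint.  A cheap certificate that the true space is small."""
    from math import comb

    C = A * (A + 1) // 2
    return comb(n + C - 1, C - 1)


def enumerate_hwe_arrays(allele_counts: np.ndarray, cap: int = _ENUM_CAP):
    """All genotype arrays consistent with the given allele copy counts.

    Yields (log_probability,) per array; returns None instead if the array space
    exceeds ``cap``.  Output probabilities sum to 1 over the space.
    """
    r = [int(c) for c in allele_counts]
    A = len(r)
    n = sum(r) // 2
    gl = gammaln(np.arange(max(n, 2 * n) + 2) + 1.0)  # gl[c] = log(c!)
    const = float(gl[n] + sum(gl[c] for c in r) - gl[2 * n])
    out: list[float] = []

    def rec(a: int, rem: list[int], h: int, lg: float) -> bool:
        if a == A:
            out.append(const + h * _LOG2 - lg)
            return len(out) <= cap
        ra = rem[a]
        # n_aa homozygotes, then distribute the leftover copies over b > a
        for naa in range(ra // 2, -1, -1):
            left = ra - 2 * naa
            if not dist(a, a + 1, left, rem, h + left, lg + gl[naa], naa):
                return False
        return True

    def dist(a: int, b: int, left: int, rem: list[int], h: int, lg: float, naa: int) -> bool:
        if left == 0:
            saved = rem[a]
            rem[a] = 0
            ok = rec(a + 1, rem, h, lg)
            rem[a] = saved
            return ok
        if b >= A:
            return True  # dead branch: copies left but no partner alleles
        avail = min(left, rem[b])
        for nab in range(avail, -1, -1):
            rem[b] -= nab
            ok = dist(a, b + 1, left - nab, rem, h, lg + gl[nab], naa)
            rem[b] += nab
            if not ok:
                return False
        return True

    if not rec(0, r, 0, 0.0):
        return None
    return np.asarray(out)


def _mc_log_probs(allele_counts: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """Log-probabilities of B genotype arrays drawn from the conditional null
    by uniform random pairing of the 2n gene copies (vectorized, chunked)."""
    A = len(allele_counts)
    copies = np.repeat(np.arange(A), allele_counts)
    n = copies.size // 2
    const = gammaln(n + 1) + float(np.sum(gammaln(allele_counts + 1))) - gammaln(2 * n + 1)
    ncode = A * A
    gl = gammaln(np.arange(n + 2) + 1.0)  # gl[c] = log(c!)
    out = np.empty(B)
    chunk = max(1, int(2_000_000 // max(ncode, 1)))
    done = 0
    while done < B:
        m = min(chunk, B - done)
        perm = rng.permuted(np.tile(copies, (m, 1)), axis=1)
        a1, a2 = perm[:, ::2], perm[:, 1::2]
        h = (a1 != a2).sum(axis=1)
        code = np.minimum(a1, a2) * A + np.maximum(a1, a2)
        flat = (code + (np.arange(m)[:, None] * ncode)).ravel()
        cnt = np.bincount(flat, minlength=m * ncode).reshape(m, ncode)
        out[done : done + m] = const + h * _LOG2 - gl[cnt].sum(axis=1)
        done += m
    return out


def hwe_test(genotypes, B: int = 10_000, seed: int = 0, enum_cap: int = _ENUM_CAP) -> TestResult:
    """Exact HWE probability test for one locus in one group.

    ``genotypes``: (n, 2) array (or list of pairs) of allele labels, missing
    excluded.  Enumeration is used when the conditional array space has at most
    ``enum_cap`` members, otherwise ``B`` Monte-Carlo pairings.
    """
    pairs = np.asarray(genotypes, dtype=np.int64).reshape(-1, 2)
    if pairs.shape[0] < 2:
        raise ValueError("HWE test needs >= 2 genotyped individuals")
    if B < 100:
        raise ValueError("B must be >= 100")
    pairs, counts = _compact(pairs)
    if counts.size < 2:
        return TestResult(statistic=0.0, p=1.0, B=0, method="skipped", flag="monomorphic")
    geno: dict[tuple[int, int], int] = {}
    for a, b in np.sort(pairs, axis=1):
        geno[(int(a), int(b))] = geno.get((int(a), int(b)), 0) + 1
    log_obs = _log_p_array(geno, counts)

    space = None
    if _space_bound(int(counts.sum()) // 2, counts.size) <= enum_cap:
        space = enumerate_hwe_arrays(counts, cap=enum_cap)
    if space is not None:
        probs = np.exp(space)
        p = float(probs[space <= log_obs + 1e-9].sum() / probs.sum())
        return TestResult(statistic=float(np.exp(log_obs)), p=min(p, 1.0), B=0,
                          method="enumeration")
    rng = np.random.default_rng(seed)
    logs = _mc_log_probs(counts, B, rng)
    hits = int((logs <= log_obs + 1e-9).sum())
    return TestResult(statistic=float(np.exp(log_obs)), p=(1 + hits) / (1 + B), B=B,
                      method="monte-carlo")


def hwe_table(gm: GenotypeMatrix, grouping=None, B: int = 10_000, seed: int = 0,
              alpha: float = 0.05) -> pd.DataFrame:
    """HWE p per (group, locus) with Holm flags across all performed tests."""
    labels = np.asarray(grouping, dtype=object) if grouping is not None else gm.group_labels
    rng = np.random.default_rng(seed)
    rows = []
    groups = []
    for g in labels:
        if g not in groups:
            groups.append(g)
    for g in groups:
        in_g = labels == g
        for l, lname in enumerate(gm.locus_names):
            ok = in_g & ~gm.missing_mask[:, l]
            if ok.sum() < 2:
                continue
            res = hwe_test(gm.calls[ok, l, :], B=B, seed=int(rng.integers(2**31 - 1)))
            rows.append({"group": g, "locus": lname, "p": res.p, "method": res.method,
                         "flag": res.flag})
    df = pd.DataFrame(rows)
    if len(df):
        adj = holm_adjust(df["p"].to_numpy(), alpha=alpha)
        df["significant"] = adj["reject"].to_numpy()
        df["holm_threshold"] = adj["threshold"].to_numpy()
    return df


# ---------------------------------------------------------------------------
# genotypic LD test
# ---------------------------------------------------------------------------

def _g_stats(c1: np.ndarray, c2mat: np.ndarray, m1: int, m2: int) -> np.ndarray:
    """G statistic per row of c2mat against fixed c1 (margins invariant)."""
    n = c1.size
    r1 = np.bincount(c1, minlength=m1).astype(float)
    r2 = np.bincount(c2mat[0], minlength=m2).astype(float)
    E = np.outer(r1, r2).ravel() / n
    rows = c2mat.shape[0]
    ncode = m1 * m2
    code = c1[None, :] * m2 + c2mat
    flat = (code + np.arange(rows)[:, None] * ncode).ravel()
    O = np.bincount(flat, minlength=rows * ncode).reshape(rows, ncode).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        G = 2.0 * xlogy(O, O / E[None, :]).sum(axis=1)
    return G


def ld_test(gm: GenotypeMatrix, group, locus_pair, B: int = 999, seed: int = 0) -> TestResult:
    """Genotypic linkage-disequilibrium G-test for one locus pair in one group."""
    if B < 100:
        raise ValueError("B must be >= 100")
    l1 = gm.locus_names.index(locus_pair[0]) if isinstance(locus_pair[0], str) else locus_pair[0]
    l2 = gm.locus_names.index(locus_pair[1]) if isinstance(locus_pair[1], str) else locus_pair[1]
    in_g = gm.group_labels == group if group is not None else np.ones(gm.n_individuals, bool)
    ok = in_g & ~gm.missing_mask[:, l1] & ~gm.missing_mask[:, l2]
    if ok.sum() < 2:
        return TestResult(0.0, 1.0, 0, "skipped", flag="too few individuals")

    def codes(l):
        pairs = gm.calls[ok, l, :]
        _, inv = np.unique(pairs[:, 0] * 10_000 + pairs[:, 1], return_inverse=True)
        return inv.astype(np.int64), int(inv.max()) + 1

    c1, m1 = codes(l1)
    c2, m2 = codes(l2)
    if m1 < 2 or m2 < 2:
        return TestResult(0.0, 1.0, 0, "skipped", flag="monomorphic locus")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(c2, (B, 1)), axis=1)
    allG = _g_stats(c1, np.vstack([c2[None, :], perms]), m1, m2)
    g_obs, g_perm = allG[0], allG[1:]
    hits = int((g_perm >= g_obs - 1e-12).sum())
    return TestResult(float(g_obs), (1 + hits) / (1 + B), B, "permutation")


def ld_table(gm: GenotypeMatrix, grouping=None, B: int = 999, seed: int = 0,
             alpha: float = 0.05) -> pd.DataFrame:
    """All within-group locus-pair LD tests, Holm-corrected across the table."""
    labels = np.asarray(grouping, dtype=object) if grouping is not None else gm.group_labels
    rng = np.random.default_rng(seed)
    gm2 = gm.with_groups(labels)
    rows = []
    for g in gm2.groups():
        for i in range(gm.n_loci):
            for j in range(i + 1, gm.n_loci):
                res = ld_test(gm2, g, (i, j), B=B, seed=int(rng.integers(2**31 - 1)))
                rows.append({
                    "group": g, "locus1": gm.locus_names[i], "locus2": gm.locus_names[j],
                    "G": res.statistic, "p": res.p, "method": res.method, "flag": res.flag,
                })
    df = pd.DataFrame(rows)
    tested = df["method"] == "permutation"
    df["significant"] = False
    if tested.any():
        adj = holm_adjust(df.loc[tested, "p"].to_numpy(), alpha=alpha)
        df.loc[tested, "significant"] = adj["reject"].to_numpy()
    return df


# ---------------------------------------------------------------------------
# sequential Bonferroni (Holm)
# ---------------------------------------------------------------------------

def holm_adjust(pvals, alpha: float = 0.05) -> pd.DataFrame:
    """Holm step-down correction.

    Sorts p ascending and rejects while p_(i) <= alpha / (m - i + 1); the first
    failure accepts all larger p-values.  Returns a frame in the input order with
    columns p, threshold, reject.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha / (m - np.arange(m))
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[order[i]] <= thresholds[i]:
            reject_sorted[i] = True
        else:
            break
    reject = np.zeros(m, dtype=bool)
    reject[order] = reject_sorted
    thr = np.empty(m)
    thr[order] = thresholds
    return pd.DataFrame({"p": p, "threshold": thr, "reject": reject})
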