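"""Numba kernels for the annealed mixture search.

The profile log-likelihood of a hard assignment z is

    sum_k sum_l [ sum_a n_kla * log(n_kla + beta) - N_kl * log(N_kl + A_l * beta) ]

which is the multinomial log-likelihood at the beta-smoothed within-cluster
frequency MLE p_kla = (n_kla + beta) / (N_kl + A_l * beta).  Single-individual
reassignment changes at most two allele counts per locus in each of two clusters,
so the move delta is O(n_loci).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _g(x, beta):
    # x * log(x + beta) with the 0 * log(beta) = 0 convention
    if x <= 0.0:
        return 0.0
    return x * np.log(x + beta)


@njit(cache=True)
def _full_loglik(counts, totals, n_alleles, beta):
    K, L = totals.shape
    out = 0.0
    for k in range(K):
        for l in range(L):
            for a in range(n_alleles[l]):
                out += _g(counts[k, l, a], beta)
            N = totals[k, l]
            if N > 0.0:
                out -= N * np.log(N + n_alleles[l] * beta)
    return out


@njit(cache=True)
def _move_delta(counts, totals, n_alleles, calls_i, k1, k2, beta):
    L = calls_i.shape[0]
    delta = 0.0
    for l in range(L):
        a = calls_i[l, 0]
        b = calls_i[l, 1]
        if a < 0:
            continue
        A = n_alleles[l]
        # remove copies from k1
        N = totals[k1, l]
        if a == b:
            c = counts[k1, l, a]
            delta += _g(c - 2.0, beta) - _g(c, beta)
        else:
            ca = counts[k1, l, a]
            cb = counts[k1, l, b]
            delta += _g(ca - 1.0, beta) - _g(ca, beta)
            delta += _g(cb - 1.0, beta) - _g(cb, beta)
        if N > 0.0:
            delta += N * np.log(N + A * beta)
        if N - 2.0 > 0.0:
            delta -= (N - 2.0) * np.log(N - 2.0 + A * beta)
        # add copies to k2
        N = totals[k2, l]
        if a == b:
            c = counts[k2, l, a]
            delta += _g(c + 2.0, beta) - _g(c, beta)
        else:
            ca = counts[k2, l, a]
            cb = counts[k2, l, b]
            delta += _g(ca + 1.0, beta) - _g(ca, beta)
            delta += _g(cb + 1.0, beta) - _g(cb, beta)
        if N > 0.0:
            delta += N * np.log(N + A * beta)
        delta -= (N + 2.0) * np.log(N + 2.0 + A * beta)
    return delta


@njit(cache=True)
def _apply_move(counts, totals, calls_i, k1, k2):
    L = calls_i.shape[0]
    for l in range(L):
        a = calls_i[l, 0]
        b = calls_i[l, 1]
        if a < 0:
            continue
        counts[k1, l, a] -= 1.0
        counts[k1, l, b] -= 1.0
        totals[k1, l] -= 2.0
        counts[k2, l, a] += 1.0
        counts[k2, l, b] += 1.0
        totals[k2, l] += 2.0


@njit(cache=True)
def anneal_mixture(calls, n_alleles, K, beta, n_sweeps, cooling, stop_sweeps, seed):
    """Metropolis annealing over single-individual reassignments.

    Returns (best_z, best_loglik, sweeps_run).  Never worse than the initial
    random state: the best-so-far assignment is tracked from initialization.
    """
    np.random.seed(seed)
    n, L, _ = calls.shape
    Amax = 0
    for l in range(L):
        if n_alleles[l] > Amax:
            Amax = n_alleles[l]
    counts = np.zeros((K, L, Amax))
    totals = np.zeros((K, L))
    z = np.empty(n, np.int64)
    for i in range(n):
        z[i] = np.random.randint(0, K)
        for l in range(L):
            a = calls[i, l, 0]
            b = calls[i, l, 1]
            if a < 0:
                continue
            counts[z[i], l, a] += 1.0
            counts[z[i], l, b] += 1.0
            totals[z[i], l] += 2.0

    loglik = _full_loglik(counts, totals, n_alleles, beta)

    # temperature scale: SD of per-individual log-likelihood contributions
    contrib = np.zeros(n)
    for i in range(n):
        k = z[i]
        s = 0.0
        for l in range(L):
            a = calls[i, l, 0]
            b = calls[i, l, 1]
            if a < 0:
                continue
            denom = totals[k, l] + n_alleles[l] * beta
            s += np.log((counts[k, l, a] + beta) / denom)
            s += np.log((counts[k, l, b] + beta) / denom)
        contrib[i] = s
    t0 = contrib.std()
    if not t0 > 0.0:
        t0 = 1.0

    best_loglik = loglik
    best_z = z.copy()
    T = t0
    quiet = 0
    sweeps_run = 0
    for _sweep in range(n_sweeps):
        accepted = 0
        for i in range(n):
            k1 = z[i]
            k2 = np.random.randint(0, K - 1)
            if k2 >= k1:
                k2 += 1
            delta = _move_delta(counts, totals, n_alleles, calls[i], k1, k2, beta)
            if delta >= 0.0 or np.random.random() < np.exp(delta / T):
                _apply_move(counts, totals, calls[i], k1, k2)
                z[i] = k2
                loglik += delta
                accepted += 1
                if loglik > best_loglik + 1e-9:
                    best_loglik = loglik
                    best_z[:] = z
        sweeps_run += 1
        if accepted == 0:
            quiet += 1
            if quiet >= stop_sweeps:
                break
        else:
            quiet = 0
        T *= cooling
    return best_z, best_loglik, sweeps_run


@njit(cache=True)
def hard_loglik(calls, n_alleles, z, K, beta):
    """Profile log-likelihood of a given hard assignment (exact recomputation)."""
    n, L, _ = calls.shape
    Amax = 0
    for l in range(L):
        if n_alleles[l] > Amax:
            Amax = n_alleles[l]
    counts = np.zeros((K, L, Amax))
    totals = np.zeros((K, L))
    for i in range(n):
        for l in range(L):
            a = calls[i, l, 0]
            b = calls[i, l, 1]
            if a < 0:
                continue
            counts[z[i], l, a] += 1.0
            counts[z[i], l, b] += 1.0
            totals[z[i], l] += 2.0
    return _full_loglik(counts, totals, n_alleles, beta)
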