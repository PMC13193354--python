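"""Maximum-likelihood mixture and admixture clustering, K-selection, panmixia test.

Two nested models over multilocus genotypes:

* **Strict mixture** — every individual belongs to exactly one of K ancestral
  demes.  The profile log-likelihood of a hard assignment (with within-cluster
  allele-frequency MLEs smoothed by a Jeffreys pseudo-count beta = 0.5) is
  maximized by Metropolis simulated annealing over single-individual
  reassignments, which keeps the search from stalling on a suboptimal peak.

* **Admixture** — each individual carries ancestry fractions q_ik on the
  K-simplex, and each gene copy of allele a at locus l has marginal probability
  sum_k q_ik p_kla.  The likelihood is maximized by EM (copy responsibilities in
  the E-step; simplex-projected count shares in the M-step), initialized from a
  mixture solution softened toward one-hot.

K is selected from replicate runs by the second-order rate of log-likelihood
change D_LK2(K) = |L(K+1) - 2 L(K) + L(K-1)| / max(SD(K), eps) — the curvature
of the mean replicate log-likelihood, normalized by the replicate SD with a
floor because replicate families frequently have zero variance.  A GST/FIS
ratio over the inferred hard clusters is reported alongside as a secondary
estimator.  Panmixia (K = 1) is tested by parametric bootstrap of the
log-likelihood gain of K = 2 over K = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin

from ._encode import EncodedGenotypes, as_encoded, encode
from ._kernels import anneal_mixture, hard_loglik
from .io_genotypes import GenotypeMatrix

__all__ = [
    "AdmixtureFit",
    "KSelectionResult",
    "MixtureClustering",
    "AdmixtureModel",
    "fit_mixture",
    "fit_admixture",
    "run_k_scan",
    "select_k",
    "panmixia_test",
    "align_clusters",
]


@dataclass
class AdmixtureFit:
    """One fitted clustering replicate (mixture or admixture)."""

    model: str                 # "mixture" | "admixture"
    K: int
    Q: np.ndarray              # (n, K), rows on the simplex (one-hot for mixture)
    P: np.ndarray              # (K, total_alleles), per-locus blocks sum to 1
    loglik: float
    seed: int
    n_iter: int
    converged: bool
    labels: np.ndarray         # hard assignment (argmax Q; ties -> lowest index)
    flag: str = ""
    loglik_path: np.ndarray | None = None

    def freqs_per_locus(self, enc: EncodedGenotypes) -> list[np.ndarray]:
        return [self.P[:, enc.offsets[l]:enc.offsets[l + 1]] for l in range(enc.n_loci)]


# ---------------------------------------------------------------------------
# strict mixture (annealed hard clustering)
# ---------------------------------------------------------------------------

def _smoothed_freqs(enc: EncodedGenotypes, z: np.ndarray, K: int, beta: float) -> np.ndarray:
    """Within-cluster allele frequencies at the beta-smoothed MLE, (K, total)."""
    total = enc.total_alleles
    counts = np.zeros((K, total))
    cp_i, cp_l, cp_col = enc.copy_arrays()
    np.add.at(counts, (z[cp_i], cp_col), 1.0)
    P = counts + beta
    sums = np.add.reduceat(P, enc.offsets[:-1], axis=1)
    return P / np.repeat(sums, enc.n_alleles, axis=1)


class MixtureClustering(ClusterMixin, BaseEstimator):
    """Strict-mixture clustering by annealed profile-likelihood search.

    Parameters
    ----------
    n_clusters : int
        Number of ancestral demes K.
    beta : float
        Pseudo-count per allele in the profiled frequency MLE (Jeffreys 0.5);
        keeps the likelihood finite when a cluster lacks an allele.
    n_sweeps, cooling, stop_sweeps : annealing schedule
        Geometric cooling from a data-scaled initial temperature (the SD of
        per-individual log-likelihood contributions), ``cooling`` per sweep,
        at most ``n_sweeps`` sweeps, stopping after ``stop_sweeps`` consecutive
        sweeps without an accepted move.
    random_state : int or None
        Seed; identical seeds give identical fits.

    Attributes (after fit)
    ----------------------
    labels_, Q_ (one-hot), cluster_freqs_, loglik_, n_iter_, n_empty_clusters_.
    """

    def __init__(self, n_clusters: int = 2, beta: float = 0.5, n_sweeps: int = 200,
                 cooling: float = 0.95, stop_sweeps: int = 5, random_state=None):
        self.n_clusters = n_clusters
        self.beta = beta
        self.n_sweeps = n_sweeps
        self.cooling = cooling
        self.stop_sweeps = stop_sweeps
        self.random_state = random_state

    def fit(self, X, y=None):
        enc = as_encoded(X)
        n = enc.n_individuals
        K = int(self.n_clusters)
        if K < 1:
            raise ValueError("n_clusters must be >= 1")
        if K > n:
            raise ValueError(f"n_clusters={K} exceeds n_individuals={n}")
        rng = np.random.default_rng(self.random_state)
        seed = int(rng.integers(2**31 - 1))
        if K == 1:
            z = np.zeros(n, dtype=np.int64)
            ll = float(hard_loglik(enc.calls, enc.n_alleles, z, 1, self.beta))
            sweeps = 0
        else:
            z, _, sweeps = anneal_mixture(
                enc.calls, enc.n_alleles, K, self.beta,
                self.n_sweeps, self.cooling, self.stop_sweeps, seed,
            )
            ll = float(hard_loglik(enc.calls, enc.n_alleles, z, K, self.beta))
        self.labels_ = np.asarray(z)
        self.loglik_ = ll
        self.n_iter_ = int(sweeps)
        self.cluster_freqs_ = _smoothed_freqs(enc, self.labels_, K, self.beta)
        Q = np.zeros((n, K))
        Q[np.arange(n), self.labels_] = 1.0
        self.Q_ = Q
        self.n_empty_clusters_ = int(K - len(np.unique(self.labels_)))
        self._enc_meta_ = (enc.n_alleles, enc.offsets)
        return self

    def predict(self, X):
        """Assign individuals to the fitted clusters by maximum likelihood."""
        enc = as_encoded(X)
        logP = np.log(self.cluster_freqs_)
        n = enc.n_individuals
        scores = np.zeros((n, self.cluster_freqs_.shape[0]))
        cp_i, _, cp_col = enc.copy_arrays()
        np.add.at(scores, cp_i, logP[:, cp_col].T)
        return np.argmax(scores, axis=1)


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

def _em_loop(enc: EncodedGenotypes, Q: np.ndarray, P: np.ndarray, tol: float,
             max_iter: int) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    cp_i, _, cp_col = enc.copy_arrays()
    n = enc.n_individuals
    K = Q.shape[1]
    ncopies = np.bincount(cp_i, minlength=n).astype(float)
    uniform = np.repeat(1.0 / enc.n_alleles, enc.n_alleles)
    path: list[float] = []
    converged = False
    for _ in range(max_iter):
        mix = Q[cp_i] * P[:, cp_col].T          # (M, K)
        tot = mix.sum(axis=1)
        ll = float(np.log(np.maximum(tot, 1e-300)).sum())
        if not np.isfinite(ll):
            return Q, P, path, False
        path.append(ll)
        if len(path) > 1 and path[-1] - path[-2] < tol:
            converged = True
            break
        r = mix / tot[:, None]
        Qacc = np.column_stack(
            [np.bincount(cp_i, weights=r[:, k], minlength=n) for k in range(K)]
        )
        Q = np.where(ncopies[:, None] > 0, Qacc / np.maximum(ncopies, 1.0)[:, None], 1.0 / K)
        Pacc = np.column_stack(
            [np.bincount(cp_col, weights=r[:, k], minlength=enc.total_alleles)
             for k in range(K)]
        )
        sums = np.add.reduceat(Pacc, enc.offsets[:-1], axis=0)      # (L, K)
        sums_rep = np.repeat(sums, enc.n_alleles, axis=0)           # (total, K)
        P = np.where(sums_rep > 0, Pacc / np.maximum(sums_rep, 1e-300),
                     uniform[:, None]).T
    return Q, P, path, converged


class AdmixtureModel(BaseEstimator):
    """Individual-ancestry (admixture) model fitted by EM.

    ``init="mixture"`` anneals a strict-mixture solution first and softens its
    one-hot Q rows to ``soften`` on the winning cluster; ``init="random"`` draws
    Q and P from flat Dirichlets.  Non-finite likelihoods trigger a fresh random
    restart (flagged).  Identical ``random_state`` gives identical fits.

    Attributes after fit: ``Q_``, ``cluster_freqs_`` (P), ``loglik_``,
    ``loglik_path_``, ``labels_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, n_clusters: int = 2, tol: float = 1e-5, max_iter: int = 300,
                 init: str = "mixture", soften: float = 0.9, beta: float = 0.5,
                 n_sweeps: int = 200, cooling: float = 0.95, stop_sweeps: int = 5,
                 random_state=None):
        self.n_clusters = n_clusters
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.soften = soften
        self.beta = beta
        self.n_sweeps = n_sweeps
        self.cooling = cooling
        self.stop_sweeps = stop_sweeps
        self.random_state = random_state

    def _init_arrays(self, enc, rng):
        K = int(self.n_clusters)
        n = enc.n_individuals
        if self.init == "mixture" and K > 1:
            mx = MixtureClustering(
                n_clusters=K, beta=self.beta, n_sweeps=self.n_sweeps,
                cooling=self.cooling, stop_sweeps=self.stop_sweeps,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(enc)
            Q = np.full((n, K), (1.0 - self.soften) / max(K - 1, 1))
            Q[np.arange(n), mx.labels_] = self.soften
            return Q, mx.cluster_freqs_.copy()
        Q = rng.dirichlet(np.ones(K), size=n)
        blocks = [rng.dirichlet(np.ones(a), size=K) for a in enc.n_alleles]
        P = np.hstack(blocks)
        return Q, P

    def fit(self, X, y=None, Q0=None, P0=None):
        enc = as_encoded(X)
        K = int(self.n_clusters)
        if K < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        rng = np.random.default_rng(self.random_state)
        flag = ""
        if Q0 is not None and P0 is not None:
            Q, P = np.asarray(Q0, float).copy(), np.asarray(P0, float).copy()
        else:
            Q, P = self._init_arrays(enc, rng)
        for attempt in range(4):
            Qf, Pf, path, converged = _em_loop(enc, Q, P, self.tol, self.max_iter)
            if path and np.isfinite(path[-1]):
                break
            flag = "restarted-nonfinite"
            K_ = K
            Q = rng.dirichlet(np.ones(K_), size=enc.n_individuals)
            P = np.hstack([rng.dirichlet(np.ones(a), size=K_) for a in enc.n_alleles])
        else:
            raise RuntimeError("admixture EM failed to reach a finite likelihood")
        self.Q_ = Qf
        self.cluster_freqs_ = Pf
        self.loglik_ = float(path[-1])
        self.loglik_path_ = np.asarray(path)
        self.labels_ = np.argmax(Qf, axis=1)
        self.n_iter_ = len(path)
        self.converged_ = bool(converged)
        self.flag_ = flag
        return self


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_mixture(gm, K: int, seed: int = 0, **kwargs) -> AdmixtureFit:
    est = MixtureClustering(n_clusters=K, random_state=seed, **kwargs).fit(gm)
    return AdmixtureFit("mixture", K, est.Q_, est.cluster_freqs_, est.loglik_,
                        seed, est.n_iter_, True, est.labels_,
                        flag="empty-cluster" if est.n_empty_clusters_ else "")


def fit_admixture(gm, K: int, seed: int = 0, tol: float = 1e-5, max_iter: int = 300,
                  init="mixture", **kwargs) -> AdmixtureFit:
    est = AdmixtureModel(n_clusters=K, tol=tol, max_iter=max_iter, init=init,
                         random_state=seed, **kwargs)
    if isinstance(init, AdmixtureFit):
        est.set_params(init="mixture")
        Q0 = np.clip(init.Q, (1.0 - 0.9) / max(K - 1, 1), 0.9)
        Q0 = Q0 / Q0.sum(axis=1, keepdims=True)
        est.fit(gm, Q0=Q0, P0=init.P)
    else:
        est.fit(gm)
    return AdmixtureFit("admixture", K, est.Q_, est.cluster_freqs_, est.loglik_,
                        seed, est.n_iter_, est.converged_, est.labels_, est.flag_,
                        loglik_path=est.loglik_path_)


def run_k_scan(gm, k_values, n_replicates: int = 10, seed: int = 0,
               model: str = "admixture", **kwargs) -> dict[int, list[AdmixtureFit]]:
    """Replicate fits for every K; each replicate gets its own derived seed."""
    enc = as_encoded(gm)
    rng = np.random.default_rng(seed)
    out: dict[int, list[AdmixtureFit]] = {}
    for K in k_values:
        fits = []
        for _ in range(n_replicates):
            s = int(rng.integers(2**31 - 1))
            if model == "mixture":
                fits.append(fit_mixture(enc, K, seed=s, **kwargs))
            else:
                fits.append(fit_admixture(enc, K, seed=s, **kwargs))
        out[K] = fits
    return out


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------

@dataclass
class KSelectionResult:
    table: pd.DataFrame        # per K: mean/sd logL, DLK1, D2 (raw), DLK2, GST, FIS, FSTIS
    chosen_k: int              # argmax D_LK2 (authoritative)
    chosen_k_fstis: int | None
    flag: str = ""
    epsilon: float = 1e-3
    panmixia_p: float | None = None


def _gst_fis(gm: GenotypeMatrix, labels: np.ndarray) -> tuple[float, float]:
    """Plug-in GST = (H_T - H_S)/H_T and FIS = 1 - H_O/H_S over inferred clusters."""
    from .differentiation import _components

    uniq = np.unique(labels)
    if uniq.size < 2:
        return 0.0, np.nan
    lut = {g: i for i, g in enumerate(uniq)}
    gidx = np.array([lut[g] for g in labels])
    hs, ht, k_eff = _components(gm, gidx, uniq.size, "plugin")
    ok = k_eff >= 2
    if not ok.any():
        return np.nan, np.nan
    mhs, mht = float(hs[ok].mean()), float(ht[ok].mean())
    miss = gm.missing_mask
    het = (gm.calls[:, :, 0] != gm.calls[:, :, 1]) & ~miss
    n_obs = (~miss).sum()
    ho = float(het.sum() / n_obs) if n_obs else 0.0
    gst = (mht - mhs) / mht if mht > 0 else 0.0
    fis = 1.0 - ho / mhs if mhs > 0 else np.nan
    return gst, fis


def select_k(fits_by_k: dict[int, list[AdmixtureFit]], gm: GenotypeMatrix | None = None,
             epsilon: float = 1e-3) -> KSelectionResult:
    """Choose K from replicate log-likelihoods by the normalized curvature D_LK2.

    D_LK2(K) = |L(K+1) - 2 L(K) + L(K-1)| / max(SD(K), epsilon) for
    2 <= K <= Kmax - 1, where L(K) and SD(K) are the mean and SD of the
    replicate log-likelihoods; ties break toward the smaller K.  If every raw
    curvature is zero the result is flagged ``no-curvature`` and K = 1 is
    returned for downstream panmixia/likelihood inspection.
    """
    ks = sorted(fits_by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K levels must be contiguous")
    if len(ks) < 3:
        raise ValueError("need at least 3 K levels for D_LK2")
    L = {k: float(np.mean([f.loglik for f in fits_by_k[k]])) for k in ks}
    SD = {k: float(np.std([f.loglik for f in fits_by_k[k]])) for k in ks}
    rows = []
    for k in ks:
        row = {"K": k, "mean_logL": L[k], "sd_logL": SD[k],
               "DLK1": L[k] - L[k - 1] if k - 1 in L else np.nan,
               "D2": np.nan, "DLK2": np.nan, "GST": np.nan, "FIS": np.nan,
               "FSTIS": np.nan}
        if k - 1 in L and k + 1 in L:
            d2 = abs(L[k + 1] - 2.0 * L[k] + L[k - 1])
            row["D2"] = d2
            row["DLK2"] = d2 / max(SD[k], epsilon)
        if gm is not None and k >= 2:
            best = max(fits_by_k[k], key=lambda f: f.loglik)
            gst, fis = _gst_fis(gm, best.labels)
            row["GST"], row["FIS"] = gst, fis
            row["FSTIS"] = gst / max(fis, epsilon) if np.isfinite(fis) else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    inner = table.dropna(subset=["DLK2"])
    flag = ""
    if inner.empty or np.allclose(inner["D2"], 0.0):
        chosen = 1
        flag = "no-curvature"
    else:
        best = inner["DLK2"].to_numpy()
        chosen = int(inner["K"].to_numpy()[int(np.argmax(best))])  # first max: smaller K
    chosen_fstis = None
    if gm is not None and table["FSTIS"].notna().any():
        sub = table.dropna(subset=["FSTIS"])
        chosen_fstis = int(sub["K"].to_numpy()[int(np.argmax(sub["FSTIS"].to_numpy()))])
    return KSelectionResult(table, chosen, chosen_fstis, flag, epsilon)


# ---------------------------------------------------------------------------
# panmixia test
# ---------------------------------------------------------------------------

def _pooled_freqs(enc: EncodedGenotypes) -> list[np.ndarray]:
    out = []
    for l in range(enc.n_loci):
        A = int(enc.n_alleles[l])
        cnt = np.zeros(A)
        col = enc.calls[:, l, :].ravel()
        col = col[col >= 0]
        np.add.at(cnt, col, 1.0)
        tot = cnt.sum()
        out.append(cnt / tot if tot > 0 else np.full(A, 1.0 / A))
    return out


def _best_delta(enc: EncodedGenotypes, R: int, rng: np.random.Generator, beta: float,
                **mix_kw) -> float:
    """best profile logL at K=2 minus logL at K=1, over R annealing replicates."""
    z1 = np.zeros(enc.n_individuals, dtype=np.int64)
    l1 = float(hard_loglik(enc.calls, enc.n_alleles, z1, 1, beta))
    best2 = -np.inf
    for _ in range(R):
        est = MixtureClustering(n_clusters=2, beta=beta,
                                random_state=int(rng.integers(2**31 - 1)), **mix_kw).fit(enc)
        best2 = max(best2, est.loglik_)
    return best2 - l1


def panmixia_test(gm, R: int = 3, B: int = 49, seed: int = 0, beta: float = 0.5,
                  **mix_kw) -> tuple[float, float]:
    """Parametric-bootstrap test of panmixia (K = 1) against K = 2.

    The statistic is the profile log-likelihood gain of the best K = 2 mixture
    fit over K = 1.  B datasets are simulated from the pooled allele-frequency
    MLE under Hardy–Weinberg with the observed missing pattern and refitted
    identically; p = (1 + #{delta_b >= delta_obs}) / (1 + B).
    """
    enc = as_encoded(gm)
    n = enc.n_individuals
    if n < 10:
        raise ValueError("panmixia test needs n >= 10")
    if B < 19:
        raise ValueError("B must be >= 19")
    rng = np.random.default_rng(seed)
    delta_obs = _best_delta(enc, R, rng, beta, **mix_kw)
    freqs = _pooled_freqs(enc)
    hits = 0
    for _ in range(B):
        calls = enc.calls.copy()
        for l in range(enc.n_loci):
            obs = calls[:, l, :] >= 0
            m = int(obs.sum())
            if m:
                calls[:, l, :][obs] = rng.choice(enc.n_alleles[l], size=m, p=freqs[l])
        sim = EncodedGenotypes(calls, enc.n_alleles, enc.offsets, enc.allele_labels, enc.ids)
        if _best_delta(sim, R, rng, beta, **mix_kw) >= delta_obs - 1e-9:
            hits += 1
    return float(delta_obs), (1 + hits) / (1 + B)


# ---------------------------------------------------------------------------
# replicate alignment
# ---------------------------------------------------------------------------

def align_clusters(Q_ref: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Column permutation matching Q's clusters to Q_ref's (max total correlation)."""
    K = Q_ref.shape[1]
    C = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = Q_ref[:, i], Q[:, j]
            sa, sb = a.std(), b.std()
            C[i, j] = float(np.corrcoef(a, b)[0, 1]) if sa > 0 and sb > 0 else -1.0
    _, cols = linear_sum_assignment(-C)
    return cols
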