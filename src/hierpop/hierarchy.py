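"""Recursive order-by-order decomposition of genetic clusters.

The defining procedure: cluster all individuals (first order), rearrange them
into the inferred clusters, then independently re-cluster each cluster (second
order), and iterate once more (third order).  Each node is gated by a panmixia
test and a minimum sample size; K at each node comes from the D_LK2 curvature
criterion over replicate admixture fits, and members pass to children by their
maximum ancestry fraction (hard assignment).  On data with nested drift this
recovers the hierarchy as successive K = 2 splits: 2 -> 4 -> 8 clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score

from ._encode import as_encoded, encode
from .admixture import (AdmixtureFit, KSelectionResult, fit_admixture,
                        panmixia_test, run_k_scan, select_k)
from .io_genotypes import GenotypeMatrix

__all__ = [
    "DecompositionNode",
    "DecompositionTree",
    "HierarchicalDecomposition",
    "decompose",
    "order_summary",
    "compare_partitions",
    "DEFAULT_K_RANGES",
]

# Highest K assayed per analysis order (capped at n // 5 at each node).
DEFAULT_K_RANGES = {1: 14, 2: 7, 3: 4}


@dataclass
class DecompositionNode:
    order: int                      # 0 = root holding all individuals
    member_idx: np.ndarray          # indices into the full individual list
    member_ids: list[str]
    chosen_k: int | None = None
    children: list = field(default_factory=list)
    kselect: KSelectionResult | None = None
    fit: AdmixtureFit | None = None
    stop_reason: str | None = None  # max_order | panmixia | too_small | no-curvature
    panmixia_p: float | None = None
    name: str = "root"

    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "order": self.order,
            "n": len(self.member_ids),
            "chosen_k": self.chosen_k,
            "stop_reason": self.stop_reason,
            "panmixia_p": self.panmixia_p,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class DecompositionTree:
    root: DecompositionNode
    individual_ids: list[str]
    max_order: int

    def nodes(self) -> list[DecompositionNode]:
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return out

    def partition_at(self, order: int) -> np.ndarray:
        """Cluster label per individual at a given order (non-split nodes carry
        their members through unchanged)."""
        labels = np.empty(len(self.individual_ids), dtype=object)

        def walk(node: DecompositionNode):
            if node.order >= order or node.is_leaf():
                labels[node.member_idx] = node.name
                return
            for c in node.children:
                walk(c)

        walk(self.root)
        return labels

    def leaf_partition(self) -> np.ndarray:
        return self.partition_at(self.max_order)

    def to_frame(self) -> pd.DataFrame:
        """Flat individual -> per-order cluster path."""
        data = {"id": self.individual_ids}
        for o in range(1, self.max_order + 1):
            data[f"order{o}"] = self.partition_at(o)
        return pd.DataFrame(data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_dict(self) -> dict:
        return self.root.to_dict()


def _check_partition(node: DecompositionNode) -> None:
    if node.is_leaf():
        return
    parts = [set(c.member_idx.tolist()) for c in node.children]
    union: set = set()
    total = 0
    for p in parts:
        union |= p
        total += len(p)
    if union != set(node.member_idx.tolist()) or total != len(node.member_idx):
        raise AssertionError(f"children of {node.name!r} do not partition the node")
    for c in node.children:
        _check_partition(c)


def decompose(
    gm: GenotypeMatrix,
    max_order: int = 3,
    k_ranges: dict[int, int] | None = None,
    n_min: int = 15,
    alpha: float = 0.05,
    n_replicates: int = 10,
    bootstrap: int = 49,
    panmixia_replicates: int = 3,
    seed: int = 0,
) -> DecompositionTree:
    """Recursive first- to ``max_order``-order decomposition.

    At each node: stop if n < ``n_min`` (too_small) or the panmixia bootstrap
    p >= ``alpha`` (panmixia); otherwise scan K = 1..Kmax(order) (Kmax capped at
    n // 5) with ``n_replicates`` admixture replicates each, choose K by D_LK2,
    hard-assign members by maximum ancestry, and recurse.  Fully seeded.
    """
    if gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    if 1.0 / (bootstrap + 1) >= alpha:
        raise ValueError(
            f"bootstrap={bootstrap} cannot resolve p < alpha={alpha}; "
            "increase bootstrap replicates")
    k_ranges = dict(DEFAULT_K_RANGES if k_ranges is None else k_ranges)
    enc = encode(gm)
    rng = np.random.default_rng(seed)

    def grow(node: DecompositionNode) -> None:
        order = node.order + 1  # the analysis order this split would create
        if order > max_order:
            node.stop_reason = "max_order"
            return
        n = len(node.member_idx)
        if n < n_min:
            node.stop_reason = "too_small"
            return
        sub = enc.subset(node.member_idx)
        delta, p = panmixia_test(sub, R=panmixia_replicates, B=bootstrap,
                                 seed=int(rng.integers(2**31 - 1)))
        node.panmixia_p = p
        if p >= alpha:
            node.stop_reason = "panmixia"
            return
        kmax = min(k_ranges.get(order, 4), max(n // 5, 3))
        sub_gm = gm.subset(node.member_idx)
        fits = run_k_scan(sub, range(1, kmax + 1), n_replicates=n_replicates,
                          seed=int(rng.integers(2**31 - 1)))
        ksel = select_k(fits, gm=sub_gm)
        ksel.panmixia_p = p
        node.kselect = ksel
        if ksel.chosen_k < 2:
            node.stop_reason = "no-curvature"
            return
        K = ksel.chosen_k
        node.chosen_k = K
        best = max(fits[K], key=lambda f: f.loglik)
        node.fit = best
        for k in range(K):
            idx = node.member_idx[best.labels == k]
            child = DecompositionNode(
                order=order,
                member_idx=idx,
                member_ids=[gm.individual_ids[i] for i in idx],
                name=f"{node.name}.{k}" if node.name != "root" else f"c{k}",
            )
            node.children.append(child)
            if idx.size:
                grow(child)
            else:
                child.stop_reason = "too_small"

    root = DecompositionNode(order=0, member_idx=np.arange(gm.n_individuals),
                             member_ids=list(gm.individual_ids))
    grow(root)
    tree = DecompositionTree(root, list(gm.individual_ids), max_order)
    _check_partition(root)
    return tree


class HierarchicalDecomposition(ClusterMixin, BaseEstimator):
    """Estimator facade over :func:`decompose`.

    After ``fit(X)`` (X a GenotypeMatrix), ``tree_`` holds the decomposition and
    ``labels_`` the leaf partition encoded as integers.
    """

    def __init__(self, max_order: int = 3, k_ranges=None, n_min: int = 15,
                 alpha: float = 0.05, n_replicates: int = 10, bootstrap: int = 49,
                 panmixia_replicates: int = 3, random_state=None):
        self.max_order = max_order
        self.k_ranges = k_ranges
        self.n_min = n_min
        self.alpha = alpha
        self.n_replicates = n_replicates
        self.bootstrap = bootstrap
        self.panmixia_replicates = panmixia_replicates
        self.random_state = random_state

    def fit(self, X, y=None):
        seed = 0 if self.random_state is None else int(self.random_state)
        self.tree_ = decompose(
            X, max_order=self.max_order, k_ranges=self.k_ranges, n_min=self.n_min,
            alpha=self.alpha, n_replicates=self.n_replicates, bootstrap=self.bootstrap,
            panmixia_replicates=self.panmixia_replicates, seed=seed,
        )
        leaf = self.tree_.leaf_partition()
        _, self.labels_ = np.unique(leaf, return_inverse=True)
        return self


# ---------------------------------------------------------------------------
# per-order diagnostics
# ---------------------------------------------------------------------------

def order_summary(tree: DecompositionTree, gm: GenotypeMatrix,
                  hwe_B: int = 2000, seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Order-wise diversity and differentiation trends.

    For each order: number of clusters, mean per-cluster N / H_O / H_E / N_A / F,
    mean pairwise Jost's D and G''ST among the order's clusters, and the mean
    number of loci conforming to HWE per cluster (Holm-corrected within the
    order).  Differentiation cells are empty when the order has one cluster.
    """
    from .diversity import diversity_table
    from .differentiation import pairwise_differentiation
    from .equilibrium import hwe_table

    rng = np.random.default_rng(seed)
    rows = []
    for order in range(1, tree.max_order + 1):
        labels = tree.partition_at(order)
        names = list(dict.fromkeys(labels))
        div = diversity_table(gm, grouping=labels)
        over = div[div["locus"] == "over loci"]
        hwe = hwe_table(gm, grouping=labels, B=hwe_B,
                        seed=int(rng.integers(2**31 - 1)), alpha=alpha)
        in_hwe = (
            hwe.assign(ok=~hwe["significant"]).groupby("group")["ok"].sum().mean()
            if len(hwe) else np.nan
        )
        row = {
            "order": order,
            "n_clusters": len(names),
            "mean_N": float(over["N"].mean()),
            "mean_H_O": float(over["H_O"].mean()),
            "mean_H_E": float(over["H_E"].mean()),
            "mean_N_A": float(over["N_A"].mean()),
            "mean_F": float(over["F"].mean()),
            "mean_loci_in_HWE": float(in_hwe),
            "mean_pairwise_D": np.nan,
            "mean_pairwise_GdblST": np.nan,
            "mean_pairwise_GST": np.nan,
        }
        if len(names) >= 2:
            pw = pairwise_differentiation(gm, grouping=labels, n_perm=0, n_boot=2,
                                          seed=int(rng.integers(2**31 - 1)))
            row["mean_pairwise_D"] = float(pw["D"].mean())
            row["mean_pairwise_GdblST"] = float(pw["G''ST"].mean())
            row["mean_pairwise_GST"] = float(pw["GST"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_partitions(inferred, true) -> tuple[float, float]:
    """(adjusted Rand index, accuracy under optimal one-to-one label matching)."""
    inferred = np.asarray(inferred)
    true = np.asarray(true)
    if inferred.shape != true.shape:
        raise ValueError("partitions must cover the same individuals")
    ari = float(adjusted_rand_score(true, inferred))
    _, a = np.unique(inferred, return_inverse=True)
    _, b = np.unique(true, return_inverse=True)
    ka, kb = a.max() + 1, b.max() + 1
    m = max(ka, kb)
    C = np.zeros((m, m))
    np.add.at(C, (a, b), 1.0)
    rows, cols = linear_sum_assignment(-C)
    acc = float(C[rows, cols].sum() / a.size)
    return ari, acc
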