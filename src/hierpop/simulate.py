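"""Synthetic genotype datasets with latent nested deme structure.

The generator encodes the hypothesis the analysis is built to detect: a balanced
binary hierarchy of breeding demes in which each level contributes its own pulse
of genetic drift.  Drift follows the Balding–Nichols construction: a child deme's
allele-frequency vector at a locus is Dirichlet-distributed around its parent's,

    p_child | p_parent ~ Dirichlet(p_parent * (1 - F) / F),

so one interpretable parameter F per level controls differentiation and nesting
composes in closed form.  Individuals are diploid Hardy–Weinberg draws within
their leaf deme (pure mode) or draw each gene copy from a leaf chosen by an
individual ancestry vector Q ~ Dirichlet(admix_alpha) (admixed mode).

Sampling-location pooling (the Wahlund device) and missing-data injection are
separate, composable steps so tests can target each effect in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .io_genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_hierarchy",
    "pool_locations",
    "assemble_locations",
    "inject_missing",
    "survey_config",
    "benchmark_config",
    "SURVEY_LOCATION_PLAN",
]


@dataclass
class SimConfig:
    """Parameters of one nested-deme simulation.

    depth
        Binary-tree depth; the pedigree has ``2**depth`` leaf demes.
    F_levels
        Per-level drift parameters in (0, 1), root-to-leaf; length must equal depth.
    n_loci, alleles_per_locus
        Number of loci and the inclusive (low, high) range the per-locus allele
        count is drawn from uniformly.
    dirichlet_theta
        Concentration of the symmetric Dirichlet the ancestral frequencies are
        drawn from (1.0 gives the flat distribution over the simplex, which for
        15-30 alleles yields expected heterozygosity near 0.9, matching highly
        polymorphic microsatellites).
    n_per_leaf
        Individuals sampled per leaf deme.
    admix_alpha
        If set, individuals are admixed with Q ~ Dirichlet(admix_alpha) over
        leaves instead of belonging to a single deme.
    missing_rate
        Per-call missing probability in [0, 1).
    """

    depth: int = 3
    F_levels: tuple = (0.12, 0.08, 0.05)
    n_loci: int = 15
    alleles_per_locus: tuple = (13, 31)
    dirichlet_theta: float = 1.0
    n_per_leaf: int = 16
    admix_alpha: float | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if len(self.F_levels) != self.depth:
            raise ValueError("len(F_levels) must equal depth")
        if any(not (0.0 < f < 1.0) for f in self.F_levels):
            raise ValueError("every F level must be in (0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        lo, hi = self.alleles_per_locus
        if not (2 <= lo <= hi):
            raise ValueError("alleles_per_locus must satisfy 2 <= low <= high")
        if self.dirichlet_theta <= 0:
            raise ValueError("dirichlet_theta must be > 0")
        if self.n_per_leaf < 1:
            raise ValueError("n_per_leaf must be >= 1")
        if self.admix_alpha is not None and self.admix_alpha <= 0:
            raise ValueError("admix_alpha must be > 0 when given")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    leaf_names: list[str]
    leaf_of: np.ndarray | None          # (n,) leaf index per individual; None if admixed
    Q: np.ndarray                       # (n, n_leaves), rows sum to 1
    leaf_freqs: list                    # per locus: (n_leaves, A_l) frequencies
    ancestral_freqs: list               # per locus: (A_l,)
    tree: dict                          # nested {"name", "F", "children"}
    F_levels: tuple = ()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def leaf_labels(self) -> np.ndarray:
        """True leaf-deme label per individual (argmax Q in admixed mode)."""
        if self.leaf_of is not None:
            idx = self.leaf_of
        else:
            idx = np.argmax(self.Q, axis=1)
        return np.array([self.leaf_names[i] for i in idx], dtype=object)

    def to_json_dict(self) -> dict:
        return {
            "leaf_names": self.leaf_names,
            "F_levels": list(self.F_levels),
            "tree": self.tree,
        }


def _grow_tree(rng: np.random.Generator, ancestral: list, depth: int, F_levels) -> tuple[list, dict]:
    """Return per-leaf frequency tables and the nested topology dict."""

    def child_freqs(freqs: list, F: float) -> list:
        out = []
        for p in freqs:
            conc = np.asarray(p) * (1.0 - F) / F
            conc = np.maximum(conc, 1e-9)  # Dirichlet needs strictly positive mass
            out.append(rng.dirichlet(conc))
        return out

    def build(freqs: list, level: int, name: str) -> tuple[list, dict]:
        if level == depth:
            return [freqs], {"name": name, "children": []}
        F = F_levels[level]
        leaves: list = []
        children = []
        for side in (0, 1):
            cf = child_freqs(freqs, F)
            sub_leaves, sub_tree = build(cf, level + 1, f"{name}{side}")
            sub_tree["F"] = F
            leaves.extend(sub_leaves)
            children.append(sub_tree)
        return leaves, {"name": name, "children": children}

    return build(ancestral, 0, "d")


def simulate_hierarchy(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate genotypes under the nested Balding–Nichols hierarchy.

    Deterministic for a given config (all randomness flows from ``cfg.seed``).
    Allele labels are 1-based integers, compatible with GenePop 2-digit codes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.alleles_per_locus
    n_all = rng.integers(lo, hi + 1, size=cfg.n_loci)
    ancestral = [rng.dirichlet(np.full(a, cfg.dirichlet_theta)) for a in n_all]

    leaf_tables, tree = _grow_tree(rng, ancestral, cfg.depth, cfg.F_levels)
    n_leaves = len(leaf_tables)
    leaf_names = [f"deme{j}" for j in range(n_leaves)]
    leaf_freqs = [
        np.vstack([leaf_tables[j][l] for j in range(n_leaves)]) for l in range(cfg.n_loci)
    ]

    n = cfg.n_per_leaf * n_leaves
    calls = np.empty((n, cfg.n_loci, 2), dtype=np.int32)
    ids = [f"ind{i + 1:04d}" for i in range(n)]

    if cfg.admix_alpha is None:
        leaf_of = np.repeat(np.arange(n_leaves), cfg.n_per_leaf)
        Q = np.zeros((n, n_leaves))
        Q[np.arange(n), leaf_of] = 1.0
        for l in range(cfg.n_loci):
            for j in range(n_leaves):
                rows = np.flatnonzero(leaf_of == j)
                draws = rng.choice(n_all[l], size=(rows.size, 2), p=leaf_freqs[l][j])
                calls[rows, l, :] = draws + 1
        groups = np.array([leaf_names[j] for j in leaf_of], dtype=object)
    else:
        leaf_of = None
        Q = rng.dirichlet(np.full(n_leaves, cfg.admix_alpha), size=n)
        for i in range(n):
            src = rng.choice(n_leaves, size=(cfg.n_loci, 2), p=Q[i])
            for l in range(cfg.n_loci):
                for s in (0, 1):
                    calls[i, l, s] = rng.choice(n_all[l], p=leaf_freqs[l][src[l, s]]) + 1
        groups = np.array(["mix"] * n, dtype=object)

    gm = GenotypeMatrix(ids, groups, [f"loc{l + 1:02d}" for l in range(cfg.n_loci)], calls)
    truth = SimTruth(leaf_names, leaf_of, Q, leaf_freqs, ancestral, tree, tuple(cfg.F_levels))
    if cfg.missing_rate > 0:
        gm = inject_missing(gm, cfg.missing_rate, seed=int(rng.integers(2**31 - 1)))
    return gm, truth


def pool_locations(
    gm: GenotypeMatrix,
    truth: SimTruth,
    mapping: Mapping[str, Mapping[str, float]],
    seed: int = 0,
) -> GenotypeMatrix:
    """Relabel individuals into sampling locations that mix leaf demes.

    ``mapping`` maps location name -> {leaf name: weight}; weights within a
    location must sum to 1.  Each individual whose true leaf appears in at least
    one location is assigned to a location with probability proportional to that
    location's weight on its leaf.  Individuals whose leaf is in no location keep
    their original label.  Genotypes and truth are untouched.
    """
    leaf_idx = {name: j for j, name in enumerate(truth.leaf_names)}
    for loc, wts in mapping.items():
        for leaf in wts:
            if leaf not in leaf_idx:
                raise ValueError(f"location {loc!r} references unknown leaf {leaf!r}")
        s = sum(wts.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights for location {loc!r} sum to {s}, expected 1")
    rng = np.random.default_rng(seed)
    true_leaves = truth.leaf_labels()
    labels = gm.group_labels.copy()
    locs = list(mapping)
    for i in range(gm.n_individuals):
        leaf = true_leaves[i]
        w = np.array([mapping[loc].get(leaf, 0.0) for loc in locs])
        if w.sum() <= 0:
            continue
        labels[i] = locs[rng.choice(len(locs), p=w / w.sum())]
    return gm.with_groups(labels)


def assemble_locations(
    gm: GenotypeMatrix,
    truth: SimTruth,
    plan: Mapping[str, tuple[int, Mapping[str, float]]],
    seed: int = 0,
) -> GenotypeMatrix:
    """Compose sampling locations of exact sizes by drawing individuals from leaves.

    ``plan`` maps location -> (sample size, {leaf: weight}).  Individuals are drawn
    without replacement from each leaf's pool; unused individuals are dropped.
    Used to mirror a field design with fixed per-location sample sizes.
    """
    rng = np.random.default_rng(seed)
    true_leaves = truth.leaf_labels()
    pools = {name: list(np.flatnonzero(true_leaves == name)) for name in truth.leaf_names}
    for p in pools.values():
        rng.shuffle(p)
    chosen: list[int] = []
    labels: list[str] = []
    for loc, (size, wts) in plan.items():
        leaves = list(wts)
        w = np.array([wts[x] for x in leaves], dtype=float)
        w = w / w.sum()
        for _ in range(size):
            order = rng.permutation(len(leaves))
            # draw a leaf by weight, falling back to any non-empty leaf
            pick = rng.choice(len(leaves), p=w)
            candidates = [pick] + [int(j) for j in order]
            for j in candidates:
                if pools[leaves[j]]:
                    chosen.append(pools[leaves[j]].pop())
                    labels.append(loc)
                    break
            else:
                raise ValueError(f"leaf pools exhausted while filling location {loc!r}")
    sub = gm.subset(chosen)
    return sub.with_groups(labels)


def inject_missing(gm: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each call to missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return gm
    rng = np.random.default_rng(seed)
    drop = rng.random((gm.n_individuals, gm.n_loci)) < rate
    calls = gm.calls.copy()
    calls[drop] = MISSING
    return GenotypeMatrix(
        list(gm.individual_ids), gm.group_labels.copy(), list(gm.locus_names), calls
    )


# ---------------------------------------------------------------------------
# canned configurations
# ---------------------------------------------------------------------------

# Four sampling locations of fixed size, each pooling one leaf from each side of
# the top split 50/50 — the strongest Wahlund mixing the topology allows.
SURVEY_LOCATION_PLAN = {
    "LocA": (20, {"deme0": 0.5, "deme4": 0.5}),
    "LocB": (40, {"deme1": 0.5, "deme5": 0.5}),
    "LocC": (40, {"deme2": 0.5, "deme6": 0.5}),
    "LocD": (40, {"deme3": 0.5, "deme7": 0.5}),
}


def survey_plan(n_per_leaf: int = 20) -> dict:
    """:data:`SURVEY_LOCATION_PLAN` with sample sizes scaled by ``n_per_leaf / 20``."""
    scale = n_per_leaf / 20.0
    return {loc: (max(2, int(round(size * scale))), dict(wts))
            for loc, (size, wts) in SURVEY_LOCATION_PLAN.items()}


def survey_config(seed: int = 0) -> SimConfig:
    """A dammed-river field-survey emulation: depth-3 deme hierarchy, 15 loci
    with 13-31 alleles, 18.6% missing calls, and enough individuals to fill 4
    sampling locations of sizes 20/40/40/40 via :data:`SURVEY_LOCATION_PLAN`."""
    return SimConfig(
        depth=3,
        F_levels=(0.12, 0.08, 0.05),
        n_loci=15,
        alleles_per_locus=(13, 31),
        dirichlet_theta=1.0,
        n_per_leaf=20,
        missing_rate=0.186,
        seed=seed,
    )


def benchmark_config(seed: int = 0) -> SimConfig:
    """Default recovery benchmark: 8 leaf demes x 16 individuals, complete data."""
    return SimConfig(
        depth=3,
        F_levels=(0.12, 0.08, 0.05),
        n_loci=15,
        alleles_per_locus=(13, 31),
        dirichlet_theta=1.0,
        n_per_leaf=16,
        missing_rate=0.0,
        seed=seed,
    )
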