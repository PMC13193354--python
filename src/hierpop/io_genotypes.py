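"""Genotype data model, GenePop/CSV readers and writers, allele binning, filtering.

The central container is :class:`GenotypeMatrix`: an individuals x loci table of
diploid calls for multiallelic codominant markers (microsatellites).  Alleles are
opaque non-negative integer labels (typically repeat-unit allele classes or GenePop
codes); a call is an unordered pair of alleles or missing.  A call where only one
allele could be scored ("half-missing") is stored as fully missing but flagged, so
every downstream statistic sees a clean genotype/no-genotype dichotomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AlleleCountTable",
    "allele_counts",
    "read_genepop",
    "write_genepop",
    "read_csv",
    "write_csv",
    "bin_fragments",
    "filter_missing",
    "GenePopParseError",
]


class GenePopParseError(ValueError):
    """Raised when GenePop-format text cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Diploid multiallelic genotypes for a set of labelled individuals.

    Parameters
    ----------
    individual_ids
        Unique labels, one per individual (row order is meaningful and preserved).
    group_labels
        Per-individual sampling-location or cluster label.
    locus_names
        Unique locus labels (column order preserved).
    calls
        int array of shape ``(n_individuals, n_loci, 2)``.  Allele labels are
        non-negative integers; ``MISSING`` (-1) in both slots marks a missing call.
        Pairs are stored sorted so that ``(a, b) == (b, a)``.
    half_missing
        Optional boolean mask of calls where exactly one allele was scored before
        the call was demoted to missing.
    """

    individual_ids: list[str]
    group_labels: np.ndarray
    locus_names: list[str]
    calls: np.ndarray
    half_missing: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individual_ids), len(self.locus_names)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci"
            )
        if len(self.group_labels) != n:
            raise ValueError("group_labels length mismatch")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if len(set(self.locus_names)) != L:
            raise ValueError("locus names must be unique")
        # normalize: unordered pairs, half-missing -> fully missing
        calls = self.calls
        one_missing = (calls == MISSING).sum(axis=2) == 1
        if self.half_missing is None:
            self.half_missing = one_missing
        else:
            self.half_missing = np.asarray(self.half_missing, dtype=bool)
        calls[one_missing] = MISSING
        self.calls = np.sort(calls, axis=2)

    # -- basic views ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def groups(self) -> list:
        """Group labels in order of first appearance."""
        seen: dict = {}
        for g in self.group_labels:
            seen.setdefault(g, None)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            self.group_labels[idx].copy(),
            list(self.locus_names),
            self.calls[idx].copy(),
            self.half_missing[idx].copy() if self.half_missing is not None else None,
        )

    def with_groups(self, labels: Sequence) -> "GenotypeMatrix":
        """Copy with new group labels (e.g. inferred cluster memberships)."""
        return GenotypeMatrix(
            list(self.individual_ids),
            np.asarray(labels, dtype=object),
            list(self.locus_names),
            self.calls.copy(),
            None if self.half_missing is None else self.half_missing.copy(),
        )

    def locus_alleles(self, l: int) -> np.ndarray:
        """Sorted unique allele labels observed at locus index ``l``."""
        col = self.calls[:, l, :].ravel()
        return np.unique(col[col != MISSING])

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and list(self.group_labels) == list(other.group_labels)
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class AlleleCountTable:
    """Per (group, locus) allele counts of gene copies.

    ``counts[g][l]`` maps allele label -> copies; ``n_ind[g][l]`` is the number of
    genotyped individuals, so copies sum to ``2 * n_ind``.
    """

    group_names: list
    locus_names: list[str]
    counts: list[list[dict[int, int]]]
    n_ind: np.ndarray  # (G, L) int

    def frequencies(self, g: int, l: int) -> dict[int, float]:
        tot = 2 * self.n_ind[g, l]
        if tot == 0:
            return {}
        return {a: c / tot for a, c in self.counts[g][l].items()}

    def pooled(self, l: int) -> dict[int, int]:
        out: dict[int, int] = {}
        for g in range(len(self.group_names)):
            for a, c in self.counts[g][l].items():
                out[a] = out.get(a, 0) + c
        return out


def allele_counts(gm: GenotypeMatrix, grouping: Sequence | None = None) -> AlleleCountTable:
    """Tabulate gene-copy counts per (group, locus).

    ``grouping`` overrides ``gm.group_labels`` (same length) — used when counting
    within inferred clusters rather than sampling locations.
    """
    labels = np.asarray(grouping, dtype=object) if grouping is not None else gm.group_labels
    if len(labels) != gm.n_individuals:
        raise ValueError("grouping length mismatch")
    group_names: list = []
    for g in labels:
        if g not in group_names:
            group_names.append(g)
    G, L = len(group_names), gm.n_loci
    counts: list[list[dict[int, int]]] = [[{} for _ in range(L)] for _ in range(G)]
    n_ind = np.zeros((G, L), dtype=int)
    gidx = {g: i for i, g in enumerate(group_names)}
    miss = gm.missing_mask
    for i in range(gm.n_individuals):
        g = gidx[labels[i]]
        for l in range(L):
            if miss[i, l]:
                continue
            a, b = int(gm.calls[i, l, 0]), int(gm.calls[i, l, 1])
            d = counts[g][l]
            d[a] = d.get(a, 0) + 1
            d[b] = d.get(b, 0) + 1
            n_ind[g, l] += 1
    return AlleleCountTable(group_names, list(gm.locus_names), counts, n_ind)


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

def read_genepop(text: str) -> GenotypeMatrix:
    """Parse GenePop-format text (2- or 3-digit allele codes, auto-detected).

    The first line is a title; locus names follow one per line or comma-separated
    on one line; population blocks are delimited by lines equal to ``Pop``
    (case-insensitive).  Individual lines are ``name , a1a2 a1a2 ...`` (comma or
    tab after the name).  Allele code ``00``/``000`` means a missing allele; a
    call with exactly one missing allele is recorded as half-missing (and treated
    as missing downstream).
    """
    lines = text.splitlines()
    if not lines:
        raise GenePopParseError("empty file")
    # locus names: lines 1.. until first Pop
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenePopParseError("no 'Pop' line found")
    if not locus_names:
        raise GenePopParseError("no locus names before first 'Pop'")
    L = len(locus_names)

    ids: list[str] = []
    groups: list[str] = []
    rows: list[list[str]] = []
    pop_no = 0
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_no += 1
            continue
        # individual line: split on first comma or tab
        if "," in stripped:
            name, _, rest = stripped.partition(",")
        elif "\t" in stripped:
            name, _, rest = stripped.partition("\t")
        else:
            raise GenePopParseError(
                f"line {lineno + 1}: no ',' or tab separating individual name"
            )
        tokens = rest.split()
        if len(tokens) != L:
            raise GenePopParseError(
                f"line {lineno + 1}: expected {L} locus tokens, got {len(tokens)}"
            )
        name = name.strip()
        if name in ids:
            raise GenePopParseError(f"line {lineno + 1}: duplicate individual id {name!r}")
        ids.append(name)
        groups.append(f"Pop{pop_no}")
        rows.append(tokens)

    if not ids:
        raise GenePopParseError("no individuals found")

    token_lens = {len(t) for row in rows for t in row}
    if token_lens == {4}:
        digits = 2
    elif token_lens == {6}:
        digits = 3
    else:
        raise GenePopParseError(
            f"inconsistent or unknown allele-code widths (token lengths {sorted(token_lens)})"
        )

    calls = np.full((len(ids), L, 2), MISSING, dtype=np.int32)
    for r, row in enumerate(rows):
        for l, tok in enumerate(row):
            a = int(tok[:digits])
            b = int(tok[digits:])
            calls[r, l, 0] = a if a != 0 else MISSING
            calls[r, l, 1] = b if b != 0 else MISSING
    return GenotypeMatrix(ids, np.array(groups, dtype=object), locus_names, calls)


def write_genepop(gm: GenotypeMatrix, digits: int = 3, title: str = "hierpop export") -> str:
    """Serialize to GenePop text.  Deterministic: input individual/locus order kept.

    Individuals are emitted in their current order; a new ``Pop`` line is started
    whenever the group label changes, so contiguous group blocks round-trip.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits
    observed = gm.calls[gm.calls != MISSING]
    if observed.size and (observed.max() >= limit or observed.min() < 1):
        raise ValueError(f"allele labels must be in [1, {limit - 1}] for {digits}-digit codes")
    out = [title]
    out.extend(gm.locus_names)
    prev_group = None
    for i in range(gm.n_individuals):
        if gm.group_labels[i] != prev_group:
            out.append("Pop")
            prev_group = gm.group_labels[i]
        toks = []
        for l in range(gm.n_loci):
            a, b = gm.calls[i, l]
            a = 0 if a == MISSING else int(a)
            b = 0 if b == MISSING else int(b)
            toks.append(f"{a:0{digits}d}{b:0{digits}d}")
        out.append(f"{gm.individual_ids[i]} , " + " ".join(toks))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# tidy CSV
# ---------------------------------------------------------------------------

def write_csv(gm: GenotypeMatrix) -> str:
    """Tidy CSV: one row per individual; columns id, group, <locus>_a, <locus>_b."""
    cols: dict[str, list] = {"id": list(gm.individual_ids), "group": list(gm.group_labels)}
    for l, name in enumerate(gm.locus_names):
        a = gm.calls[:, l, 0]
        b = gm.calls[:, l, 1]
        cols[f"{name}_a"] = ["" if x == MISSING else int(x) for x in a]
        cols[f"{name}_b"] = ["" if x == MISSING else int(x) for x in b]
    return pd.DataFrame(cols).to_csv(index=False)


def read_csv(text: str) -> GenotypeMatrix:
    import io as _io

    df = pd.read_csv(_io.StringIO(text), dtype={"id": str, "group": str})
    if "id" not in df.columns or "group" not in df.columns:
        raise ValueError("CSV must have 'id' and 'group' columns")
    locus_cols = [c for c in df.columns if c.endswith("_a")]
    locus_names = [c[:-2] for c in locus_cols]
    n, L = len(df), len(locus_names)
    calls = np.full((n, L, 2), MISSING, dtype=np.int32)
    for l, name in enumerate(locus_names):
        for slot, suffix in enumerate(("_a", "_b")):
            col = pd.to_numeric(df[name + suffix], errors="coerce")
            vals = col.to_numpy()
            ok = ~np.isnan(vals)
            calls[ok, l, slot] = vals[ok].astype(np.int32)
    return GenotypeMatrix(
        list(df["id"]), df["group"].to_numpy(dtype=object), locus_names, calls
    )


# ---------------------------------------------------------------------------
# allele binning from raw fragment lengths
# ---------------------------------------------------------------------------

def bin_fragments(lengths: Iterable[float], motif_len: int) -> tuple[dict[float, int], pd.DataFrame]:
    """Snap raw fragment sizes (bp) to a repeat-unit grid of allele classes.

    Searches grid offsets in ``[0, motif_len)`` at 0.1-bp resolution for the one
    minimizing total squared deviation of every length from its nearest grid point
    ``offset + k * motif_len``.  Returns the mapping length -> integer allele class
    and a per-length residual report, so a human can supervise ambiguous bins.
    """
    lengths = [float(x) for x in lengths]
    if not lengths:
        raise ValueError("no fragment lengths supplied")
    if any(x <= 0 for x in lengths):
        raise ValueError("fragment lengths must be positive")
    motif_len = int(motif_len)
    if motif_len < 2:
        raise ValueError("motif_len must be >= 2")

    arr = np.asarray(lengths)
    offsets = np.arange(0.0, motif_len, 0.1)
    # residual of x to nearest grid point for every candidate offset
    rel = (arr[None, :] - offsets[:, None]) / motif_len
    resid = (rel - np.round(rel)) * motif_len
    totals = (resid**2).sum(axis=1)
    best = int(np.argmin(totals))  # ties -> smallest offset
    off = offsets[best]
    k = np.round((arr - off) / motif_len).astype(int)
    base = int(round(off))
    classes = base + k * motif_len
    residuals = arr - (off + k * motif_len)
    report = pd.DataFrame(
        {
            "length": arr,
            "allele_class": classes,
            "residual": residuals,
            "offset": off,
        }
    )
    mapping = {x: int(c) for x, c in zip(lengths, classes)}
    return mapping, report


# ---------------------------------------------------------------------------
# missing-data filtering
# ---------------------------------------------------------------------------

def filter_missing(gm: GenotypeMatrix, max_missing_loci: int) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals with strictly more than ``max_missing_loci`` missing calls.

    Survivor order is preserved and surviving genotypes are untouched.  Returns the
    filtered matrix and the ids removed.
    """
    if not (0 <= max_missing_loci <= gm.n_loci):
        raise ValueError("max_missing_loci out of range")
    n_miss = gm.missing_mask.sum(axis=1)
    keep = np.flatnonzero(n_miss <= max_missing_loci)
    removed = [gm.individual_ids[i] for i in np.flatnonzero(n_miss > max_missing_loci)]
    if keep.size == 0:
        raise ValueError("filter would remove every individual")
    if removed:
        return gm.subset(keep), removed
    return gm, removed
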