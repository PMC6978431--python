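"""Locus Set Enrichment Analysis (LSEA).

Gene set enrichment for GWAS signal that works on genomic *loci* rather than
genes, so that a block of linked variants spanning several functionally
related, genetically linked genes is counted once.  The procedure:

1. **Clumping** — genome-wide significant variants are greedily grouped
   around the lowest-p-value index SNP using an r-squared threshold within a
   base-pair window (a re-implementation of PLINK's clump procedure).
2. **Locus intervals** — each clump becomes the interval spanning its
   leftmost to rightmost member; intervals are merged when they overlap by
   more than 70% of the shorter interval or span different parts of the same
   gene; intervals touching the MHC region or the HIST1 gene cluster on
   chromosome 6 (extreme LD, gene-dense) are dropped.
3. **Locus universe** — loci from every trait are merged into a disjoint,
   sorted interval universe: all possible loci bearing GWAS signal.
4. **Interval gene sets** — a gene set is mapped onto the universe: a
   universe interval belongs to the set if at least one member gene overlaps
   it (counted once however many member genes it spans).
5. **Enrichment** — for a query locus list hitting n distinct universe
   intervals, the statistic F is the number of hit intervals belonging to
   the set; the p-value is the upper hypergeometric tail P(X >= F) with
   population N = |universe| and K = |set in universe|, Holm-adjusted across
   sets (Benjamini-Hochberg available behind a flag).

All interval arithmetic is 0-based half-open.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .gwas_io import normalize_chrom

logger = logging.getLogger(__name__)

# Extreme-LD exclusion regions (hg19), given as 1-based inclusive coordinates
# chr6:28,866,528-33,775,446 (MHC) and chr6:25,000,528-28,000,446 (HIST1),
# stored 0-based half-open.
MHC_REGION = ("6", 28_866_527, 33_775_446, "MHC")
HIST1_REGION = ("6", 25_000_527, 28_000_446, "HIST1")


@dataclass(frozen=True)
class Region:
    """A named genomic region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"malformed region {self.name or ''} [{self.start},{self.end})")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return (
            normalize_chrom(chrom) == normalize_chrom(self.chrom)
            and start < self.end
            and end > self.start
        )


DEFAULT_EXCLUSIONS: tuple[Region, ...] = (Region(*MHC_REGION), Region(*HIST1_REGION))


# ---------------------------------------------------------------------------
# gene annotation and LD sources
# ---------------------------------------------------------------------------


class GeneAnnotation:
    """Gene bodies from a BED4 table (chrom, start, end, symbol; 0-based half-open)."""

    def __init__(self, table: pd.DataFrame):
        required = ["chrom", "start", "end", "symbol"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"gene annotation is missing columns {missing}")
        df = table.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            raise ValueError("malformed gene annotation: need 0 <= start < end")
        self.table = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.table.groupby("chrom"):
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), sym) for s, e, sym in zip(sub["start"], sub["end"], sub["symbol"])
            )
        self._span: dict[str, tuple[int, int]] = {
            str(r.symbol): (r.chrom, int(r.start), int(r.end))  # type: ignore[misc]
            for r in self.table.itertuples(index=False)
        }

    @classmethod
    def read_bed(cls, path: str | Path) -> "GeneAnnotation":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "symbol"],
            dtype={"chrom": str, "symbol": str}, comment="#",
        )
        return cls(df)

    def write_bed(self, path: str | Path) -> None:
        self.table[["chrom", "start", "end", "symbol"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @property
    def symbols(self) -> set[str]:
        return set(self._span)

    def locate(self, symbol: str) -> tuple[str, int, int] | None:
        return self._span.get(symbol)

    def overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        """Symbols of genes overlapping [start, end) by >= 1 bp."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


class LDTable:
    """Pairwise r-squared lookup, symmetric, sparse.

    Pairs absent from the table are treated as r-squared 0; callers that hit
    absent pairs log one summary warning per operation rather than one per
    pair, since sparse LD tables routinely omit below-threshold pairs.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float]):
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), v in pairs.items():
            v = float(v)
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"r2 must lie in [0,1], got {v} for ({a},{b})")
            self._r2[(a, b) if a <= b else (b, a)] = min(v, 1.0)
        self.missing_queries = 0

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        val = self._r2.get(key)
        if val is None:
            self.missing_queries += 1
            return 0.0
        return val

    @classmethod
    def read_pairs(cls, path: str | Path) -> "LDTable":
        df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
        missing = {"id_a", "id_b", "r2"} - set(df.columns)
        if missing:
            raise ValueError(f"LD table is missing columns {sorted(missing)}")
        return cls({(a, b): float(v) for a, b, v in zip(df["id_a"], df["id_b"], df["r2"])})

    @classmethod
    def from_genotypes(cls, genotypes: pd.DataFrame) -> "LDTable":
        """r-squared as squared Pearson correlation of genotype dosage rows.

        ``genotypes``: variants x samples dosage matrix indexed by variant id.
        Monomorphic variants yield r2 = 0 against everything.
        """
        ids = [str(i) for i in genotypes.index]
        arr = genotypes.to_numpy(dtype=float)
        sd = arr.std(axis=1)
        keep = sd > 0
        pairs: dict[tuple[str, str], float] = {}
        if keep.sum() >= 2:
            corr = np.corrcoef(arr[keep])
            kept = [i for i, k in zip(range(len(ids)), keep) if k]
            for x, y in itertools.combinations(range(len(kept)), 2):
                a, b = ids[kept[x]], ids[kept[y]]
                pairs[(a, b)] = float(corr[x, y] ** 2)
        return cls(pairs)

    def write_pairs(self, path: str | Path) -> None:
        pd.DataFrame(
            [(a, b, v) for (a, b), v in sorted(self._r2.items())],
            columns=["id_a", "id_b", "r2"],
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------


@dataclass
class ClumpVariant:
    """Minimal variant view used for clumping: id, coordinates, p-value."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    pvalue: float


@dataclass
class Clump:
    """A greedy LD clump: the index SNP and all variants assigned to it."""

    index_variant: ClumpVariant
    members: list[ClumpVariant]  # includes the index variant
    chrom: str

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open span of member coordinates."""
        positions = [m.pos for m in self.members]
        return (min(positions) - 1, max(positions))


def clump_variants(
    significant: Sequence[ClumpVariant],
    ld: LDTable,
    r2_threshold: float = 0.5,
    window_kb: int = 250,
) -> list[Clump]:
    """Greedy PLINK-style LD clumping.

    Repeatedly take the unassigned variant with the smallest p-value as the
    index (ties broken by chrom, pos, variant id), and assign to its clump
    every unassigned variant on the same chromosome within ``window_kb`` of
    the index with r-squared >= ``r2_threshold``.  Every input variant ends
    up in exactly one clump.
    """
    window_bp = int(window_kb) * 1000
    pending = sorted(significant, key=lambda v: (v.pvalue, v.chrom, v.pos, v.variant_id))
    assigned: set[str] = set()
    missing_before = ld.missing_queries
    clumps: list[Clump] = []
    for idx in pending:
        if idx.variant_id in assigned:
            continue
        assigned.add(idx.variant_id)
        members = [idx]
        for v in pending:
            if v.variant_id in assigned or v.chrom != idx.chrom:
                continue
            if abs(v.pos - idx.pos) <= window_bp and ld.r2(idx.variant_id, v.variant_id) >= r2_threshold:
                assigned.add(v.variant_id)
                members.append(v)
        clumps.append(Clump(index_variant=idx, members=members, chrom=idx.chrom))
    missed = ld.missing_queries - missing_before
    if missed:
        logger.warning("%d LD pair(s) absent from the table were treated as r2=0", missed)
    return clumps


# ---------------------------------------------------------------------------
# loci and universe
# ---------------------------------------------------------------------------


@dataclass
class LocusInterval:
    """A genomic locus interval derived from one or more clumps."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    source_clumps: tuple[int, ...] = ()
    index_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid locus interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def _overlap_len(a: LocusInterval, b: LocusInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _merge_pair(a: LocusInterval, b: LocusInterval) -> LocusInterval:
    return LocusInterval(
        chrom=a.chrom,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        source_clumps=tuple(sorted(set(a.source_clumps) | set(b.source_clumps))),
        index_variants=tuple(sorted(set(a.index_variants) | set(b.index_variants))),
    )


def build_loci(
    clumps: Sequence[Clump],
    genes: GeneAnnotation | None = None,
    exclusions: Sequence[Region] = DEFAULT_EXCLUSIONS,
    merge_overlap: float = 0.7,
) -> list[LocusInterval]:
    """Turn clumps into merged, exclusion-filtered locus intervals.

    Each clump spans its leftmost-to-rightmost member.  Intervals are then
    iteratively merged (to a fixed point) when they overlap by strictly more
    than ``merge_overlap`` of the *shorter* interval, or when both overlap
    the same gene body by >= 1 bp ("span different parts of the same gene").
    Finally any interval overlapping an exclusion region by >= 1 bp is
    dropped.
    """
    intervals = [
        LocusInterval(
            chrom=c.chrom,
            start=c.span[0],
            end=c.span[1],
            source_clumps=(i,),
            index_variants=(c.index_variant.variant_id,),
        )
        for i, c in enumerate(clumps)
    ]
    intervals = _merge_to_fixed_point(intervals, genes, merge_overlap)
    kept = [
        iv
        for iv in intervals
        if not any(r.overlaps(iv.chrom, iv.start, iv.end) for r in exclusions)
    ]
    return sorted(kept, key=lambda iv: (iv.chrom, iv.start, iv.end))


def _should_merge(
    a: LocusInterval, b: LocusInterval, genes: GeneAnnotation | None, merge_overlap: float
) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = _overlap_len(a, b)
    if ov > merge_overlap * min(a.length, b.length):
        return True
    if genes is not None:
        if genes.overlapping(a.chrom, a.start, a.end) & genes.overlapping(b.chrom, b.start, b.end):
            return True
    return False


def _merge_to_fixed_point(
    intervals: list[LocusInterval], genes: GeneAnnotation | None, merge_overlap: float
) -> list[LocusInterval]:
    merged = True
    intervals = list(intervals)
    while merged:
        merged = False
        intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        out: list[LocusInterval] = []
        for iv in intervals:
            if out and _should_merge(out[-1], iv, genes, merge_overlap):
                out[-1] = _merge_pair(out[-1], iv)
                merged = True
            else:
                # same-gene merges can join non-adjacent intervals; check all
                hit = None
                for j, prev in enumerate(out[:-1]):
                    if _should_merge(prev, iv, genes, merge_overlap):
                        hit = j
                        break
                if hit is not None:
                    out[hit] = _merge_pair(out[hit], iv)
                    merged = True
                else:
                    out.append(iv)
        intervals = out
    return intervals


class LocusUniverse:
    """Disjoint, sorted locus intervals over the whole dataset."""

    def __init__(self, intervals: Sequence[LocusInterval]):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom and a.end > b.start:
                raise ValueError("universe intervals must be pairwise disjoint")
        self.intervals: list[LocusInterval] = list(ivs)
        self._trees: dict[str, IntervalTree] = {}
        for i, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    def __len__(self) -> int:
        return len(self.intervals)

    def hits(self, chrom: str, start: int, end: int) -> set[int]:
        """Indices of universe intervals overlapping [start, end) by >= 1 bp."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def write_bed(self, path: str | Path) -> None:
        pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, f"u{i}") for i, iv in enumerate(self.intervals)]
        ).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed(cls, path: str | Path) -> "LocusUniverse":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "name"],
            dtype={"chrom": str},
        )
        return cls(
            [LocusInterval(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples(index=False)]
        )


def write_loci_bed(path: str | Path, loci: Sequence[LocusInterval]) -> None:
    pd.DataFrame(
        [
            (iv.chrom, iv.start, iv.end, ",".join(iv.index_variants) or f"locus{i}")
            for i, iv in enumerate(loci)
        ]
    ).to_csv(path, sep="\t", header=False, index=False)


def build_universe(per_trait_loci: Mapping[str, Sequence[LocusInterval]]) -> LocusUniverse:
    """Merge all traits' loci into the disjoint locus universe (any-overlap union)."""
    pool = [iv for loci in per_trait_loci.values() for iv in loci]
    if not pool:
        raise ValueError("empty universe")
    pool.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[LocusInterval] = []
    for iv in pool:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            merged[-1] = _merge_pair(merged[-1], iv)
        else:
            merged.append(iv)
    return LocusUniverse(merged)


# ---------------------------------------------------------------------------
# gene sets and enrichment
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read an MSigDB-dialect GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(path: str | Path, sets: Mapping[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


@dataclass
class IntervalGeneSet:
    """A gene set mapped onto the locus universe (member interval indices)."""

    set_name: str
    universe_members: frozenset[int]


def build_interval_gene_sets(
    gene_sets: Mapping[str, Sequence[str]],
    genes: GeneAnnotation,
    universe: LocusUniverse,
) -> list[IntervalGeneSet]:
    """Map each gene set to the universe intervals it overlaps.

    A universe interval belongs to a set if at least one member gene overlaps
    it by >= 1 bp; an interval spanning several member genes is counted once.
    Symbols missing from the annotation are logged and skipped.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    gene_hits: dict[str, set[int]] = {}
    out: list[IntervalGeneSet] = []
    unresolved: set[str] = set()
    for name in gene_sets:
        members: set[int] = set()
        for sym in gene_sets[name]:
            if sym not in gene_hits:
                loc = genes.locate(sym)
                if loc is None:
                    unresolved.add(sym)
                    gene_hits[sym] = set()
                else:
                    gene_hits[sym] = universe.hits(*loc)
            members |= gene_hits[sym]
        out.append(IntervalGeneSet(set_name=name, universe_members=frozenset(members)))
    if unresolved:
        logger.warning(
            "%d gene symbol(s) not found in the annotation were skipped", len(unresolved)
        )
    return out


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one gene set in a query locus list."""

    set_name: str
    F: int
    n_query: int
    K_set: int
    N_universe: int
    pvalue: float
    p_adjusted: float = float("nan")


def hypergeom_upper_tail(F: int, N: int, K: int, n: int) -> float:
    """P(X >= F) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= F <= min(n, K)):
        raise ValueError(f"inconsistent hypergeometric counts F={F} N={N} K={K} n={n}")
    return float(hypergeom.sf(F - 1, N, K, n))


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Sort ascending, adj_(i) = max(adj_(i-1), (m-i+1) * p_(i)) capped at 1,
    mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (false discovery rate control)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lsea_enrich(
    query_loci: Sequence[LocusInterval],
    interval_sets: Sequence[IntervalGeneSet],
    universe: LocusUniverse,
    adjust: str = "holm",
) -> list[EnrichmentResult]:
    """Locus-set enrichment of a query locus list against the universe.

    Each query locus is mapped to the universe interval(s) it overlaps (a
    locus overlapping several universe intervals contributes each once); n is
    the number of distinct universe intervals hit.  For each set,
    F = number of hit intervals in the set and p = P(X >= F) under the
    hypergeometric null.  Results are sorted by raw p-value.
    """
    if adjust not in ("holm", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    hit: set[int] = set()
    for iv in query_loci:
        h = universe.hits(iv.chrom, iv.start, iv.end)
        if not h:
            raise ValueError(
                f"query locus {iv.chrom}:{iv.start}-{iv.end} overlaps no universe interval; "
                "query loci must be built with the universe's exclusion and merge rules"
            )
        hit |= h
    N = len(universe)
    n = len(hit)
    results = []
    for s in interval_sets:
        K = len(s.universe_members)
        F = len(hit & s.universe_members)
        results.append(
            EnrichmentResult(
                set_name=s.set_name, F=F, n_query=n, K_set=K, N_universe=N,
                pvalue=hypergeom_upper_tail(F, N, K, n),
            )
        )
    adj = (holm_adjust if adjust == "holm" else bh_adjust)([r.pvalue for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    results.sort(key=lambda r: (r.pvalue, r.set_name))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name, "F": r.F, "n": r.n_query, "K": r.K_set,
                "N": r.N_universe, "p": r.pvalue, "p_adjusted": r.p_adjusted,
            }
            for r in results
        ],
        columns=["set", "F", "n", "K", "N", "p", "p_adjusted"],
    )


def shared_cluster_enrichments(
    per_trait_results: Mapping[str, Sequence[EnrichmentResult]],
    clustering,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster "union of gene sets": sets enriched in >= 2 member traits.

    For each cluster, retain gene sets with adjusted p < ``alpha`` in two or
    more member traits, with the count of enriched traits.  Clusters with
    fewer than two traits yield no rows.
    """
    rows = []
    for cluster, traits in sorted(clustering.members().items()):
        if len(traits) < 2:
            continue
        tally: dict[str, int] = {}
        for t in traits:
            if t not in per_trait_results:
                raise ValueError(f"no enrichment results for trait {t!r}")
            for r in per_trait_results[t]:
                if r.p_adjusted < alpha:
                    tally[r.set_name] = tally.get(r.set_name, 0) + 1
        for name, count in sorted(tally.items()):
            if count >= 2:
                rows.append({"cluster_id": cluster, "set": name, "n_enriched_traits": count})
    return pd.DataFrame(rows, columns=["cluster_id", "set", "n_enriched_traits"])
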