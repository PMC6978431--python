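"""Pleiotropy score and stratification of pleiotropic variants.

Even after clustering, distinct trait clusters can remain substantially
correlated, so a variant associated with two clusters may simply reflect
vertical pleiotropy (one trait mediating the other).  The pleiotropy score
quantifies this: for a variant associated with clusters C_1..C_N,

    PS = -log10( prod over pairs n < m of corr(C_n, C_m) )

where corr(C_n, C_m) is the maximum absolute phenotypic correlation between
any member trait pair — an upper bound on how much cluster correlation alone
could explain the joint association.  A low PS means the multi-cluster
association is plausibly driven by trait correlation; variants with PS <= 2
are removed, leaving "biologically" (horizontally) pleiotropic variants.

Variants are then stratified by degree of pleiotropy (number of associated
clusters >= cutoff, for cutoffs 2, 3, ...), with loci re-derived by clumping
and merging each stratum and genome coverage reported per stratum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lsea import (
    Clump,
    ClumpVariant,
    DEFAULT_EXCLUSIONS,
    GeneAnnotation,
    LDTable,
    LocusInterval,
    Region,
    build_loci,
    clump_variants,
)
from .trait_clustering import ClusterCorrelationMatrix

logger = logging.getLogger(__name__)

#: Multiplicative floor applied inside the pair product before the log, so
#: that high-degree variants with many small pair correlations do not
#: underflow to an artificial infinity.
PRODUCT_FLOOR = 1e-300

#: Default PS filter boundary: variants with PS <= 2 are removed.
DEFAULT_PS_THRESHOLD = 2.0


def pleiotropy_score(clusters: Iterable[str], cluster_corr: ClusterCorrelationMatrix) -> float:
    """PS = -log10 of the product of pairwise cluster correlations.

    Defined for two or more clusters.  If any pair has correlation exactly 0
    the score is +infinity (the association cannot be explained by trait
    correlation at all); otherwise the product is floored at 1e-300 before
    the log to avoid underflow.
    """
    cl = sorted(set(clusters))
    if len(cl) < 2:
        raise ValueError("PS undefined below degree 2")
    missing = [c for c in cl if c not in cluster_corr.clusters]
    if missing:
        raise ValueError(f"cluster(s) absent from correlation matrix: {missing}")
    product = 1.0
    for i, a in enumerate(cl):
        for b in cl[i + 1 :]:
            v = cluster_corr.pair(a, b)
            if v == 0.0:
                return math.inf
            product *= v
    return -math.log10(max(product, PRODUCT_FLOOR))


@dataclass
class PleiotropyRecord:
    """Per-variant pleiotropy summary: associated clusters, degree, and PS."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    associated_clusters: frozenset[str]
    degree: int
    ps: float
    min_pvalue: float
    retained: bool = False

    def __post_init__(self) -> None:
        if self.degree != len(self.associated_clusters):
            raise ValueError("degree must equal the number of associated clusters")
        if self.degree < 2:
            raise ValueError("pleiotropy records are defined for degree >= 2 only")


def pleiotropy_records(
    cluster_matrix,
    cluster_corr: ClusterCorrelationMatrix,
    ps_threshold: float = DEFAULT_PS_THRESHOLD,
) -> list[PleiotropyRecord]:
    """Score every multi-cluster variant of a variant x cluster matrix.

    Variants associated with a single cluster are excluded entirely.  The
    ``retained`` flag marks variants passing the filter (PS strictly greater
    than ``ps_threshold``; +infinity always passes).
    """
    if cluster_matrix.unit != "cluster":
        raise ValueError("expected an association matrix over clusters")
    records: list[PleiotropyRecord] = []
    grouped = cluster_matrix.entries.groupby("variant_id", sort=True)
    for variant_id, sub in grouped:
        clusters = frozenset(sub["group"])
        if len(clusters) < 2:
            continue
        ps = pleiotropy_score(clusters, cluster_corr)
        records.append(
            PleiotropyRecord(
                variant_id=str(variant_id),
                chrom=str(sub["chrom"].iloc[0]),
                pos=int(sub["pos"].iloc[0]),
                associated_clusters=clusters,
                degree=len(clusters),
                ps=ps,
                min_pvalue=float(sub["pvalue"].min()),
                retained=ps > ps_threshold,
            )
        )
    return records


def select_pleiotropic_variants(
    cluster_matrix,
    cluster_corr: ClusterCorrelationMatrix,
    ps_threshold: float = DEFAULT_PS_THRESHOLD,
) -> list[PleiotropyRecord]:
    """High-confidence "biologically" pleiotropic variants (PS > threshold)."""
    return [r for r in pleiotropy_records(cluster_matrix, cluster_corr, ps_threshold) if r.retained]


def records_table(records: Sequence[PleiotropyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "degree": r.degree,
                "clusters": ",".join(sorted(r.associated_clusters)),
                "ps": "inf" if math.isinf(r.ps) else r.ps,
                "retained": r.retained,
            }
            for r in records
        ],
        columns=["variant_id", "chrom", "pos", "degree", "clusters", "ps", "retained"],
    )


@dataclass
class LocusBuilder:
    """Clump-and-merge configuration for re-deriving loci from a variant set."""

    ld: LDTable
    genes: GeneAnnotation | None = None
    exclusions: Sequence[Region] = DEFAULT_EXCLUSIONS
    r2_threshold: float = 0.5
    window_kb: int = 250
    merge_overlap: float = 0.7

    def build(self, variants: Sequence[ClumpVariant]) -> list[LocusInterval]:
        if not variants:
            return []
        clumps = clump_variants(
            variants, self.ld, r2_threshold=self.r2_threshold, window_kb=self.window_kb
        )
        return build_loci(
            clumps, self.genes, exclusions=self.exclusions, merge_overlap=self.merge_overlap
        )


@dataclass
class PleiotropyStratum:
    """Variants with degree >= cutoff, their loci, and total genome coverage."""

    cutoff: int
    variants: list[PleiotropyRecord]
    loci: list[LocusInterval]
    total_length_bp: int


def stratify_by_degree(
    records: Sequence[PleiotropyRecord],
    locus_builder: LocusBuilder,
    cutoffs: Sequence[int] = tuple(range(2, 11)),
) -> list[PleiotropyStratum]:
    """Stratify (pre-filtered) pleiotropic variants by degree-of-pleiotropy cutoff.

    For each cutoff t, the stratum holds variants associated with >= t
    clusters; loci are re-derived by clumping and merging those variants and
    the summed locus length reports genome coverage.  Strata are nested and
    an empty stratum has zero length.
    """
    strata: list[PleiotropyStratum] = []
    for t in cutoffs:
        sub = [r for r in records if r.degree >= t]
        cvs = [
            ClumpVariant(variant_id=r.variant_id, chrom=r.chrom, pos=r.pos, pvalue=r.min_pvalue)
            for r in sub
        ]
        loci = locus_builder.build(cvs)
        strata.append(
            PleiotropyStratum(
                cutoff=int(t),
                variants=sub,
                loci=loci,
                total_length_bp=int(sum(iv.length for iv in loci)),
            )
        )
    return strata


def strata_summary(strata: Sequence[PleiotropyStratum]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cutoff": s.cutoff,
                "n_variants": len(s.variants),
                "n_loci": len(s.loci),
                "total_length_bp": s.total_length_bp,
            }
            for s in strata
        ],
        columns=["cutoff", "n_variants", "n_loci", "total_length_bp"],
    )
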