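"""End-to-end phenome pipeline: ingest -> cluster -> LSEA -> pleiotropy score.

Thin orchestration over the analysis modules, used by the command-line
interface and by recovery experiments on simulated phenomes.  Every step is
an exported function of its own module; this file only wires them together
and carries the run's intermediate products in a single result object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gwas_io, lsea, pleiotropy, trait_clustering
from .gwas_io import AssociationMatrix, TraitMeta, VariantRecord
from .lsea import (
    DEFAULT_EXCLUSIONS,
    ClumpVariant,
    EnrichmentResult,
    GeneAnnotation,
    IntervalGeneSet,
    LDTable,
    LocusInterval,
    LocusUniverse,
    Region,
)
from .pleiotropy import LocusBuilder, PleiotropyRecord, PleiotropyStratum
from .trait_clustering import (
    ClusterCorrelationMatrix,
    TraitClustering,
    TraitCorrelationMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Tunable thresholds of a pipeline run (defaults follow the method)."""

    h2_alpha: float = gwas_io.HERITABILITY_ALPHA
    p_threshold: float = gwas_io.GENOME_WIDE_ALPHA
    r2_threshold: float = 0.5
    window_kb: int = 250
    merge_overlap: float = 0.7
    exclusions: Sequence[Region] = DEFAULT_EXCLUSIONS
    ps_threshold: float = pleiotropy.DEFAULT_PS_THRESHOLD
    enrichment_alpha: float = 0.05
    adjust: str = "holm"
    corr_source: str = "proxy"  # "proxy" (null z-scores) or "input" (given matrix)
    null_p_floor: float = 1e-4  # variants with min p >= this count as null for the proxy
    linkage: str = "average"


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    params: PipelineParams
    matrix: AssociationMatrix
    trait_corr: TraitCorrelationMatrix
    clustering: TraitClustering
    cluster_matrix: AssociationMatrix
    cluster_corr: ClusterCorrelationMatrix
    per_trait_loci: dict[str, list[LocusInterval]]
    universe: LocusUniverse
    interval_sets: list[IntervalGeneSet]
    per_trait_enrichment: dict[str, list[EnrichmentResult]]
    shared_enrichments: pd.DataFrame
    records: list[PleiotropyRecord]
    retained: list[PleiotropyRecord]
    pleiotropic_loci: list[LocusInterval]
    pleiotropic_enrichment: list[EnrichmentResult]
    strata: list[PleiotropyStratum]

    def summaries(self) -> dict:
        return {
            "traits": gwas_io.phenome_summary(self.matrix),
            "clusters": gwas_io.phenome_summary(self.cluster_matrix),
        }


def records_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    """Turn a summary-stat table (reader dialect) into VariantRecords."""
    schema = gwas_io.DEFAULT_SCHEMA
    return [
        VariantRecord(
            variant_id=str(getattr(r, schema["variant_id"])),
            chrom=str(getattr(r, schema["chrom"])),
            pos=int(getattr(r, schema["pos"])),
            ref=str(getattr(r, schema["ref"])),
            alt=str(getattr(r, schema["alt"])),
            maf=float(getattr(r, schema["maf"])),
            beta=float(getattr(r, schema["beta"])),
            se=float(getattr(r, schema["se"])),
            pvalue=float(getattr(r, schema["pvalue"])),
        )
        for r in df.itertuples(index=False)
    ]


def _clump_variants_of(records: Sequence[VariantRecord]) -> list[ClumpVariant]:
    return [
        ClumpVariant(variant_id=r.variant_id, chrom=r.chrom, pos=r.pos, pvalue=r.pvalue)
        for r in records
    ]


def run_pipeline(
    stats: Mapping[str, pd.DataFrame],
    trait_meta: Sequence[TraitMeta],
    ld: LDTable,
    genes: GeneAnnotation,
    gene_sets: Mapping[str, Sequence[str]],
    trait_corr: TraitCorrelationMatrix | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full phenome analysis on in-memory inputs.

    ``stats`` maps trait id to its full summary-statistic table.  With
    ``params.corr_source == "proxy"`` the phenotypic correlation is estimated
    from null-variant z-scores (beta/se at variants whose best p-value is
    above ``null_p_floor`` in every trait); with ``"input"`` the supplied
    ``trait_corr`` is used directly.
    """
    params = params or PipelineParams()

    # 1. heritability filter and per-trait significance
    heritable = gwas_io.filter_heritable(list(trait_meta), alpha=params.h2_alpha)
    kept = [t.trait_id for t in heritable if t.trait_id in stats]
    if len(kept) < 3:
        raise ValueError("need at least 3 heritable traits with summary statistics")
    per_trait_sig: dict[str, list[VariantRecord]] = {}
    for trait_id in kept:
        records = records_from_frame(stats[trait_id])
        per_trait_sig[trait_id] = gwas_io.select_significant(records, params.p_threshold)
    matrix = gwas_io.build_association_matrix(per_trait_sig)

    # 2. trait correlation
    if params.corr_source == "input":
        if trait_corr is None:
            raise ValueError('corr_source="input" requires a trait correlation matrix')
        corr = TraitCorrelationMatrix(trait_corr.values.loc[kept, kept])
    elif params.corr_source == "proxy":
        zcols, pcols = {}, {}
        for trait_id in kept:
            df = stats[trait_id]
            zcols[trait_id] = (
                df[gwas_io.DEFAULT_SCHEMA["beta"]] / df[gwas_io.DEFAULT_SCHEMA["se"]]
            ).to_numpy()
            pcols[trait_id] = df[gwas_io.DEFAULT_SCHEMA["pvalue"]].to_numpy()
        zmat = pd.DataFrame(zcols)
        pmat = np.column_stack([pcols[t] for t in kept])
        null_mask = pmat.min(axis=1) >= params.null_p_floor
        corr = trait_clustering.estimate_trait_correlation_proxy(zmat, null_mask)
    else:
        raise ValueError(f"unknown corr_source {params.corr_source!r}")

    # 3. clustering and cluster-level association matrix
    clustering = trait_clustering.cluster_traits(corr, linkage=params.linkage)
    cluster_matrix = trait_clustering.assign_cluster_associations(matrix, clustering)
    cluster_corr = trait_clustering.cluster_pair_correlation(corr, clustering)

    # 4. per-trait loci and the locus universe
    per_trait_loci: dict[str, list[LocusInterval]] = {}
    for trait_id in kept:
        if not per_trait_sig[trait_id]:
            per_trait_loci[trait_id] = []
            continue
        clumps = lsea.clump_variants(
            _clump_variants_of(per_trait_sig[trait_id]), ld,
            r2_threshold=params.r2_threshold, window_kb=params.window_kb,
        )
        per_trait_loci[trait_id] = lsea.build_loci(
            clumps, genes, exclusions=params.exclusions, merge_overlap=params.merge_overlap
        )
    universe = lsea.build_universe(per_trait_loci)
    interval_sets = lsea.build_interval_gene_sets(gene_sets, genes, universe)

    # 5. per-trait enrichment and per-cluster shared gene sets
    per_trait_enrichment: dict[str, list[EnrichmentResult]] = {}
    for trait_id in kept:
        loci = per_trait_loci[trait_id]
        per_trait_enrichment[trait_id] = (
            lsea.lsea_enrich(loci, interval_sets, universe, adjust=params.adjust) if loci else []
        )
    shared = lsea.shared_cluster_enrichments(
        per_trait_enrichment, clustering, alpha=params.enrichment_alpha
    )

    # 6. pleiotropy score, filter, loci of pleiotropic variants, strata
    records = pleiotropy.pleiotropy_records(cluster_matrix, cluster_corr, params.ps_threshold)
    retained = [r for r in records if r.retained]
    builder = LocusBuilder(
        ld=ld, genes=genes, exclusions=params.exclusions,
        r2_threshold=params.r2_threshold, window_kb=params.window_kb,
        merge_overlap=params.merge_overlap,
    )
    pleio_loci = builder.build(
        [
            ClumpVariant(variant_id=r.variant_id, chrom=r.chrom, pos=r.pos, pvalue=r.min_pvalue)
            for r in retained
        ]
    )
    pleio_enrichment = (
        lsea.lsea_enrich(pleio_loci, interval_sets, universe, adjust=params.adjust)
        if pleio_loci
        else []
    )
    strata = pleiotropy.stratify_by_degree(retained, builder)

    return PipelineResult(
        params=params, matrix=matrix, trait_corr=corr, clustering=clustering,
        cluster_matrix=cluster_matrix, cluster_corr=cluster_corr,
        per_trait_loci=per_trait_loci, universe=universe, interval_sets=interval_sets,
        per_trait_enrichment=per_trait_enrichment, shared_enrichments=shared,
        records=records, retained=retained, pleiotropic_loci=pleio_loci,
        pleiotropic_enrichment=pleio_enrichment, strata=strata,
    )


def run_on_bundle(bundle, params: PipelineParams | None = None) -> PipelineResult:
    """Run the pipeline on a simulated phenome bundle."""
    return run_pipeline(
        stats=bundle.stats,
        trait_meta=bundle.trait_meta,
        ld=bundle.ld,
        genes=GeneAnnotation(bundle.genes),
        gene_sets=bundle.gene_sets,
        trait_corr=bundle.trait_corr,
        params=params,
    )
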