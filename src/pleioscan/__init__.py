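"""pleioscan: phenome-wide pleiotropy analysis from GWAS summary statistics.

Trait clustering by phenotypic correlation, locus set enrichment analysis
(LSEA), pleiotropy-score filtering of multi-cluster associations, annotation
class overrepresentation, and a synthetic phenome generator with ground
truth for method validation.
"""

from .gwas_io import (
    AssociationMatrix,
    TraitMeta,
    VariantRecord,
    build_association_matrix,
    filter_heritable,
    phenome_summary,
    read_summary_stats,
    read_trait_meta,
    select_significant,
)
from .trait_clustering import (
    ClusterCorrelationMatrix,
    TraitClustering,
    TraitCorrelationMatrix,
    assign_cluster_associations,
    cluster_pair_correlation,
    cluster_traits,
    estimate_trait_correlation_proxy,
)
from .lsea import (
    Clump,
    ClumpVariant,
    DEFAULT_EXCLUSIONS,
    EnrichmentResult,
    GeneAnnotation,
    HIST1_REGION,
    IntervalGeneSet,
    LDTable,
    LocusInterval,
    LocusUniverse,
    MHC_REGION,
    Region,
    bh_adjust,
    build_interval_gene_sets,
    build_loci,
    build_universe,
    clump_variants,
    holm_adjust,
    hypergeom_upper_tail,
    lsea_enrich,
    read_gmt,
    shared_cluster_enrichments,
    write_gmt,
)
from .pleiotropy import (
    LocusBuilder,
    PleiotropyRecord,
    PleiotropyStratum,
    pleiotropy_records,
    pleiotropy_score,
    select_pleiotropic_variants,
    stratify_by_degree,
)
from .overrep import (
    AnnotationTable,
    OverrepResult,
    class_overrep,
    region_overrep,
    two_by_two_overrep,
)
from .synthetic_data import SimBundle, SimConfig, TruthTable, expected_truth_report, simulate_phenome
from .pipeline import PipelineParams, PipelineResult, run_on_bundle, run_pipeline

__version__ = "0.1.0"
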