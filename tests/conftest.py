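import pytest

from pleioscan import SimConfig, run_on_bundle, simulate_phenome

#: Scaled-down phenome used by most tests: 12 traits in 4 clusters, 1,100
#: variants of which 300 sit in 30 LD blocks hosting 30 planted causal
#: variants (8 horizontal, 8 vertical, 14 trait-specific).
SMALL = dict(
    n_traits=12,
    n_clusters=4,
    n_variants=1100,
    n_ld_blocks=30,
    n_null_variants=800,
    n_horizontal=8,
    n_vertical=8,
    n_trait_specific=14,
    n_genes=60,
    n_gene_sets=10,
    planted_enriched_sets=1,
    genome_length_bp=7_500_000,
    n_chromosomes=2,
)


def small_config(seed: int = 11, **overrides) -> SimConfig:
    return SimConfig(seed=seed, **{**SMALL, **overrides})


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_phenome(small_config())


@pytest.fixture(scope="session")
def small_result(small_bundle):
    return run_on_bundle(small_bundle)
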