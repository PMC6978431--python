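"""Synthetic phenome generator with known ground truth.

Generates, at the summary-statistic level, everything the pipeline consumes:
per-trait GWAS summary statistics whose null-variant z-scores follow a
multivariate normal with block-structured trait correlation (clusters of
correlated traits), LD blocks defining pairwise r-squared, planted causal
variants of three architectures, genes tiling the genome, and gene sets with
planted enrichment — plus a truth table recording every planted fact, so
recovery can be scored exactly.

Planted architectures:

* **horizontal** — independent effects on traits drawn from several distinct,
  weakly correlated clusters (default 3); the variants the pleiotropy-score
  filter should *retain*.
* **vertical** — effects on two traits inside one highly correlated cluster;
  after correct clustering these variants touch a single cluster and must
  *not* appear among pleiotropic variants.
* **trait_specific** — an effect on a single trait.

Each causal variant sits at the focal position of its own LD block; the
other block members receive the attenuated mean shift sqrt(r2) * effect_z,
as expected for markers in LD with a causal allele, so clumps and loci have
realistic extent.  Null z-scores are independent across variants (LD shapes
effects only, not noise) — a deliberate simplification.

p-values are two-sided normal tails of z; effect sizes are beta = z * se
with se from the usual 1/sqrt(2 * maf * (1-maf) * n_samples).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import gwas_io
from .gwas_io import TraitMeta
from .lsea import LDTable
from .trait_clustering import TraitCorrelationMatrix

logger = logging.getLogger(__name__)

_ALLELES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic phenome.

    Defaults describe a phenome of 40 traits in 8 clusters of 5 (within-
    cluster |r| 0.8, cross-cluster |r| 0.02), 5,000 variants on 2
    chromosomes of which 3,000 are null and 2,000 belong to 200 LD blocks
    (r-squared 0.8 within a block, 0 between), 200 planted causal variants
    (50 horizontal across 3 clusters, 50 vertical, 100 trait-specific) with
    standardized effect z = 8, 400 genes tiling 50 Mb, and 30 gene sets of
    which 2 are planted on the genes at horizontal-pleiotropic loci.
    """

    seed: int = 0
    n_traits: int = 40
    n_clusters: int = 8
    within_cluster_corr: float = 0.8
    cross_cluster_corr: float = 0.02
    n_variants: int = 5000
    n_ld_blocks: int = 200
    block_r2: float = 0.8
    n_null_variants: int = 3000
    n_horizontal: int = 50
    n_vertical: int = 50
    n_trait_specific: int = 100
    horizontal_span: int = 3
    effect_z: float = 8.0
    n_genes: int = 400
    n_gene_sets: int = 30
    planted_enriched_sets: int = 2
    genome_length_bp: int = 50_000_000
    n_chromosomes: int = 2
    n_samples: int = 300_000

    def validate(self) -> None:
        if not (0.0 <= self.cross_cluster_corr <= self.within_cluster_corr <= 1.0):
            raise ValueError("need 0 <= cross_cluster_corr <= within_cluster_corr <= 1")
        if not (0.0 <= self.block_r2 <= 1.0):
            raise ValueError("block_r2 must lie in [0,1]")
        if self.n_clusters < 1 or self.n_traits < self.n_clusters:
            raise ValueError("need n_traits >= n_clusters >= 1")
        n_causal = self.n_horizontal + self.n_vertical + self.n_trait_specific
        if n_causal > self.n_ld_blocks:
            raise ValueError("planted causal count exceeds the number of LD blocks")
        if self.n_null_variants + self.block_size * self.n_ld_blocks != self.n_variants:
            raise ValueError(
                "n_variants must equal n_null_variants + n_ld_blocks * block_size "
                f"(block_size={self.block_size})"
            )
        if self.block_size < 1:
            raise ValueError("each LD block needs at least one variant")
        if self.horizontal_span < 2 or self.horizontal_span > self.n_clusters:
            raise ValueError("horizontal_span must lie in [2, n_clusters]")
        if self.n_vertical > 0 and self.n_traits // self.n_clusters < 2:
            raise ValueError("vertical pleiotropy needs clusters with >= 2 traits")
        if self.planted_enriched_sets > self.n_gene_sets:
            raise ValueError("planted_enriched_sets must not exceed n_gene_sets")
        if self.planted_enriched_sets > 0 and self.n_horizontal < self.planted_enriched_sets:
            raise ValueError("need at least one horizontal variant per planted set")
        if self.n_genes < 2 * self.n_ld_blocks:
            raise ValueError("need n_genes >= 2 * n_ld_blocks (one gene tile between blocks)")

    @property
    def block_size(self) -> int:
        return (self.n_variants - self.n_null_variants) // max(self.n_ld_blocks, 1)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown simulation option(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class TruthTable:
    """Ground truth of one simulated phenome."""

    trait_clusters: dict[str, str]  # trait_id -> true cluster id
    variant_class: dict[str, str]  # variant_id -> null|horizontal|vertical|trait_specific|ld_proxy
    causal_targets: dict[str, list[str]]  # focal variant -> target trait ids
    causal_gene: dict[str, str]  # focal variant -> nearest gene symbol
    enriched_sets: list[str]
    focal_variants: dict[str, list[str]]  # class -> focal variant ids

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimBundle:
    """In-memory simulated phenome: inputs for every pipeline stage plus truth."""

    config: SimConfig
    trait_meta: list[TraitMeta]
    stats: dict[str, pd.DataFrame]  # trait_id -> summary-stat table (reader dialect)
    zscores: pd.DataFrame  # variants x traits
    trait_corr: TraitCorrelationMatrix  # target (generating) correlation
    ld: LDTable
    ld_pairs: pd.DataFrame
    genes: pd.DataFrame  # chrom, start, end, symbol
    gene_sets: dict[str, list[str]]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        """Emit the bundle as files in the dialects the pipeline reads."""
        out = Path(outdir)
        (out / "stats").mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        gwas_io.write_trait_meta(out / "traits.tsv", self.trait_meta)
        for trait_id in sorted(self.stats):
            self.stats[trait_id].to_csv(out / "stats" / f"{trait_id}.tsv", sep="\t", index=False)
        self.trait_corr.write(out / "trait_corr.tsv")
        self.ld_pairs.to_csv(out / "ld.tsv", sep="\t", index=False)
        self.genes[["chrom", "start", "end", "symbol"]].to_csv(
            out / "genes.bed", sep="\t", header=False, index=False
        )
        from .lsea import write_gmt

        write_gmt(out / "sets.gmt", self.gene_sets)
        self.truth.to_json(out / "truth.json")


def _trait_layout(config: SimConfig) -> tuple[list[str], dict[str, str], np.ndarray]:
    """Trait ids, true cluster labels, and the generating correlation matrix."""
    traits = [f"T{i + 1:03d}" for i in range(config.n_traits)]
    # contiguous, near-equal cluster sizes
    sizes = np.full(config.n_clusters, config.n_traits // config.n_clusters)
    sizes[: config.n_traits % config.n_clusters] += 1
    labels: dict[str, str] = {}
    assign = np.repeat(np.arange(config.n_clusters), sizes)
    for t, c in zip(traits, assign):
        labels[t] = f"K{c + 1}"
    sigma = np.full((config.n_traits, config.n_traits), config.cross_cluster_corr)
    same = assign[:, None] == assign[None, :]
    sigma[same] = config.within_cluster_corr
    np.fill_diagonal(sigma, 1.0)
    return traits, labels, sigma


def _genome_layout(config: SimConfig, rng: np.random.Generator):
    """Place genes, LD blocks, and null variants on the simulated genome.

    Genes tile the genome contiguously.  Each LD block is anchored at the
    start of every (n_genes / n_ld_blocks)-th gene tile so a block's span
    stays inside a single, distinct gene — planted causal loci then map to
    genes unambiguously.
    """
    chrom_len = config.genome_length_bp // config.n_chromosomes
    gene_len = config.genome_length_bp // config.n_genes
    genes_per_chrom = config.n_genes // config.n_chromosomes
    gene_rows = []
    for g in range(config.n_genes):
        chrom = str(g // genes_per_chrom + 1)
        start = (g % genes_per_chrom) * gene_len
        gene_rows.append(
            {"chrom": chrom, "start": start, "end": min(start + gene_len, chrom_len),
             "symbol": f"GENE{g + 1:04d}"}
        )
    genes = pd.DataFrame(gene_rows)

    tiles_per_block = config.n_genes // config.n_ld_blocks
    spacing = max(1, int(gene_len * 0.7) // max(config.block_size, 1))
    block_rows = []
    for b in range(config.n_ld_blocks):
        g = b * tiles_per_block
        anchor = genes.iloc[g]
        for m in range(config.block_size):
            block_rows.append(
                {"variant_id": f"b{b:03d}_{m}", "chrom": anchor["chrom"],
                 "pos": int(anchor["start"]) + 1000 + m * spacing + 1,  # 1-based
                 "block": b, "member": m}
            )
    block_df = pd.DataFrame(block_rows)

    null_rows = []
    for j in range(config.n_null_variants):
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        null_rows.append(
            {"variant_id": f"null{j:04d}", "chrom": chrom,
             "pos": int(rng.integers(1, chrom_len + 1)), "block": -1, "member": -1}
        )
    null_df = pd.DataFrame(null_rows)
    variants = pd.concat([block_df, null_df], ignore_index=True)
    variants = variants.sort_values(["chrom", "pos", "variant_id"], kind="stable").reset_index(
        drop=True
    )
    return genes, variants


def simulate_phenome(config: SimConfig) -> SimBundle:
    """Generate a complete synthetic phenome; fully determined by config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    traits, true_labels, sigma = _trait_layout(config)
    genes, variants = _genome_layout(config, rng)
    n_var = len(variants)

    # null z-scores: MVN with the target trait correlation, iid across variants
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n_var, config.n_traits)) @ chol.T

    # assign causal classes to LD blocks
    n_causal = config.n_horizontal + config.n_vertical + config.n_trait_specific
    causal_blocks = rng.permutation(config.n_ld_blocks)[:n_causal]
    classes = (
        ["horizontal"] * config.n_horizontal
        + ["vertical"] * config.n_vertical
        + ["trait_specific"] * config.n_trait_specific
    )

    cluster_members: dict[str, list[str]] = {}
    for t, c in true_labels.items():
        cluster_members.setdefault(c, []).append(t)
    clusters = sorted(cluster_members)
    multi_clusters = [c for c in clusters if len(cluster_members[c]) >= 2]

    trait_index = {t: i for i, t in enumerate(traits)}
    block_of = variants["block"].to_numpy()
    member_of = variants["member"].to_numpy()
    focal_member = (config.block_size - 1) // 2
    attenuation = np.sqrt(config.block_r2)

    variant_class = {v: "null" for v in variants["variant_id"]}
    causal_targets: dict[str, list[str]] = {}
    causal_gene: dict[str, str] = {}
    focal_variants: dict[str, list[str]] = {"horizontal": [], "vertical": [], "trait_specific": []}
    tiles_per_block = config.n_genes // config.n_ld_blocks

    for b, cls in zip(causal_blocks, classes):
        if cls == "horizontal":
            chosen = rng.choice(clusters, size=config.horizontal_span, replace=False)
            targets = [str(rng.choice(cluster_members[c])) for c in chosen]
        elif cls == "vertical":
            c = str(rng.choice(multi_clusters))
            targets = [str(t) for t in rng.choice(cluster_members[c], size=2, replace=False)]
        else:
            targets = [str(rng.choice(traits))]
        rows = np.flatnonzero(block_of == b)
        cols = [trait_index[t] for t in targets]
        for r in rows:
            shift = config.effect_z * (1.0 if member_of[r] == focal_member else attenuation)
            z[r, cols] += shift
            vid = variants["variant_id"].iloc[r]
            variant_class[vid] = cls if member_of[r] == focal_member else "ld_proxy"
        focal_id = f"b{b:03d}_{focal_member}"
        focal_variants[cls].append(focal_id)
        causal_targets[focal_id] = targets
        causal_gene[focal_id] = f"GENE{b * tiles_per_block + 1:04d}"

    # planted gene sets: genes hosting horizontal-pleiotropic loci, split
    # round-robin across the planted sets; decoys are random gene samples
    gene_sets: dict[str, list[str]] = {}
    horizontal_genes = [causal_gene[v] for v in focal_variants["horizontal"]]
    for s in range(config.planted_enriched_sets):
        gene_sets[f"PLANTED_SET_{s + 1}"] = sorted(horizontal_genes[s :: config.planted_enriched_sets])
    all_symbols = genes["symbol"].to_numpy()
    for s in range(config.n_gene_sets - config.planted_enriched_sets):
        size = int(rng.integers(10, 31))
        gene_sets[f"RANDOM_SET_{s + 1}"] = sorted(rng.choice(all_symbols, size=size, replace=False))

    # summary statistics
    maf = rng.uniform(0.01, 0.5, size=n_var)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_samples)
    pvals = 2.0 * norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    ref = rng.choice(_ALLELES, size=n_var)
    alt_offset = rng.integers(1, 4, size=n_var)
    alt = _ALLELES[(np.searchsorted(_ALLELES, ref) + alt_offset) % 4]

    stats: dict[str, pd.DataFrame] = {}
    for j, trait_id in enumerate(traits):
        stats[trait_id] = pd.DataFrame(
            {
                "variant": variants["variant_id"],
                "chrom": variants["chrom"],
                "pos": variants["pos"],
                "ref": ref,
                "alt": alt,
                "minor_AF": maf,
                "beta": z[:, j] * se,
                "se": se,
                "pval": pvals[:, j],
            }
        )

    trait_meta = [
        TraitMeta(t, f"synthetic trait {t} (cluster {true_labels[t]})",
                  float(rng.uniform(0.05, 0.5)), float(rng.uniform(0.0, 0.04)))
        for t in traits
    ]

    pair_rows = []
    for b in range(config.n_ld_blocks):
        ids = [f"b{b:03d}_{m}" for m in range(config.block_size)]
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                pair_rows.append({"id_a": ids[x], "id_b": ids[y], "r2": config.block_r2})
    ld_pairs = pd.DataFrame(pair_rows, columns=["id_a", "id_b", "r2"])
    ld = LDTable({(r["id_a"], r["id_b"]): r["r2"] for r in pair_rows})

    zscores = pd.DataFrame(z, index=variants["variant_id"].to_numpy(), columns=traits)
    trait_corr = TraitCorrelationMatrix(pd.DataFrame(sigma, index=traits, columns=traits))
    truth = TruthTable(
        trait_clusters=true_labels,
        variant_class=variant_class,
        causal_targets=causal_targets,
        causal_gene=causal_gene,
        enriched_sets=sorted(k for k in gene_sets if k.startswith("PLANTED_SET_")),
        focal_variants=focal_variants,
    )
    return SimBundle(
        config=config, trait_meta=trait_meta, stats=stats, zscores=zscores,
        trait_corr=trait_corr, ld=ld, ld_pairs=ld_pairs, genes=genes,
        gene_sets=gene_sets, truth=truth,
    )


def expected_truth_report(truth: TruthTable, result) -> dict:
    """Score a pipeline run against the generator's ground truth.

    ``result`` is a :class:`pleioscan.pipeline.PipelineResult`.  Reports the
    recovered cluster count and adjusted-Rand agreement with the true trait
    partition, pleiotropy-score sensitivity on horizontal and rejection rate
    on vertical planted variants, and the p-value ranks of the planted
    enriched gene sets in the pleiotropic-locus enrichment results.
    """
    from sklearn.metrics import adjusted_rand_score

    recovered = result.clustering.labels
    missing = set(truth.trait_clusters) - set(recovered)
    if missing:
        raise ValueError(f"pipeline result lacks cluster labels for traits: {sorted(missing)}")
    order = sorted(truth.trait_clusters)
    ari = float(
        adjusted_rand_score([truth.trait_clusters[t] for t in order], [recovered[t] for t in order])
    )

    retained_ids = {r.variant_id for r in result.retained}
    horizontal = truth.focal_variants.get("horizontal", [])
    vertical = truth.focal_variants.get("vertical", [])
    sensitivity = (
        sum(v in retained_ids for v in horizontal) / len(horizontal) if horizontal else float("nan")
    )
    rejection = (
        sum(v not in retained_ids for v in vertical) / len(vertical) if vertical else float("nan")
    )

    ranks: dict[str, int] = {}
    ordered_sets = [r.set_name for r in result.pleiotropic_enrichment]
    for name in truth.enriched_sets:
        if name not in ordered_sets:
            raise ValueError(f"planted set {name!r} absent from enrichment results")
        ranks[name] = ordered_sets.index(name) + 1
    return {
        "recovered_k": result.clustering.k,
        "true_k": len(set(truth.trait_clusters.values())),
        "cluster_ari": ari,
        "horizontal_sensitivity": float(sensitivity),
        "vertical_rejection": float(rejection),
        "planted_set_ranks": ranks,
    }
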