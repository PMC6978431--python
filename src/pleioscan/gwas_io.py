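"""Reading, filtering and merging of per-trait GWAS summary statistics.

The entry point of the pipeline: per-trait TSV files of association summary
statistics (variant, coordinates, alleles, MAF, effect size, standard error,
p-value) plus a trait metadata table carrying partitioned-heritability
estimates.  Traits without significant non-zero heritability (h2 p >= 0.05)
are dropped, genome-wide significant variants (p < 5e-9) are retained per
trait, and everything is merged into a single sparse variant x trait
association matrix that all downstream steps consume.

Variant identity is the tuple (chrom, pos, ref, alt); the textual variant id
is carried along but never trusted for joins, since summary-statistic
releases disagree on rsID coverage.  Positions are 1-based in input files
(GWAS convention) and converted to 0-based half-open only inside interval
code.  Each alt allele of a multi-allelic site is a distinct variant.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default column layout: a minimal Neale-lab-like summary-statistic TSV.
DEFAULT_SCHEMA: dict[str, str] = {
    "variant_id": "variant",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "maf": "minor_AF",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
}

#: Genome-wide significance threshold used throughout (strict "<").
GENOME_WIDE_ALPHA = 5e-9

#: Heritability significance threshold (strict "<").
HERITABILITY_ALPHA = 0.05


class SchemaError(ValueError):
    """A required column is missing from a summary-statistic file."""


class ParseError(ValueError):
    """A data row could not be parsed; the message names the offending row."""


class ConsistencyError(ValueError):
    """The same variant id maps to conflicting coordinates across files."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so 'chr6' and '6' compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class TraitMeta:
    """One phenotype with its partitioned-heritability estimate."""

    trait_id: str
    description: str
    h2_estimate: float
    h2_pvalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_pvalue <= 1.0):
            raise ValueError(
                f"h2_pvalue must lie in [0,1], got {self.h2_pvalue} for {self.trait_id}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One variant's association summary statistics for one trait."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float
    beta: float
    se: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must lie in (0,1], got {self.pvalue}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Coordinate-based identity (chrom, pos, ref, alt)."""
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)


_NUMERIC_FIELDS = ("maf", "beta", "se", "pvalue")


def read_summary_stats(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[VariantRecord]:
    """Read one trait's summary statistics from a tab-separated file.

    Parameters
    ----------
    path
        TSV (optionally gzipped) with a header row.
    schema
        Mapping from the field names of :class:`VariantRecord` to column
        names in the file; defaults to :data:`DEFAULT_SCHEMA`.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ParseError
        If a numeric field cannot be parsed; the message names the data row
        (1-based, excluding the header).
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    missing = set(DEFAULT_SCHEMA) - set(schema)
    if missing:
        raise SchemaError(f"schema is missing required fields: {sorted(missing)}")

    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    absent = [col for col in schema.values() if col not in df.columns]
    if absent:
        raise SchemaError(f"{path}: missing required column(s) {absent}")

    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = {f: getattr(row, col) for f, col in schema.items()}
        try:
            pos = int(raw["pos"])
            nums = {f: float(raw[f]) for f in _NUMERIC_FIELDS}
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: cannot parse data row {i}: {exc}") from exc
        if any(not np.isfinite(v) for v in nums.values()):
            bad = [f for f, v in nums.items() if not np.isfinite(v)]
            raise ParseError(f"{path}: cannot parse data row {i}: non-finite {bad}")
        try:
            records.append(
                VariantRecord(
                    variant_id=str(raw["variant_id"]),
                    chrom=normalize_chrom(raw["chrom"]),
                    pos=pos,
                    ref=str(raw["ref"]),
                    alt=str(raw["alt"]),
                    **nums,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: invalid data row {i}: {exc}") from exc
    return records


def write_summary_stats(
    path: str | Path,
    records: Iterable[VariantRecord],
    schema: Mapping[str, str] | None = None,
) -> None:
    """Write records in the same TSV dialect :func:`read_summary_stats` reads."""
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    rows = [{col: getattr(r, f) for f, col in schema.items()} for r in records]
    df = pd.DataFrame(rows, columns=list(schema.values()))
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_trait_meta(path: str | Path) -> list[TraitMeta]:
    """Read the trait metadata table (trait_id, description, h2, h2_pvalue)."""
    df = pd.read_csv(path, sep="\t")
    required = {"trait_id", "description", "h2_estimate", "h2_pvalue"}
    absent = required - set(df.columns)
    if absent:
        raise SchemaError(f"{path}: missing required column(s) {sorted(absent)}")
    return [
        TraitMeta(str(r.trait_id), str(r.description), float(r.h2_estimate), float(r.h2_pvalue))
        for r in df.itertuples(index=False)
    ]


def write_trait_meta(path: str | Path, traits: Iterable[TraitMeta]) -> None:
    pd.DataFrame(
        [
            {
                "trait_id": t.trait_id,
                "description": t.description,
                "h2_estimate": t.h2_estimate,
                "h2_pvalue": t.h2_pvalue,
            }
            for t in traits
        ]
    ).to_csv(path, sep="\t", index=False)


def filter_heritable(
    traits: Sequence[TraitMeta], alpha: float = HERITABILITY_ALPHA
) -> list[TraitMeta]:
    """Keep traits with significant non-zero heritability (h2 p strictly < alpha)."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0,1], got {alpha}")
    return [t for t in traits if t.h2_pvalue < alpha]


def select_significant(
    records: Sequence[VariantRecord], threshold: float = GENOME_WIDE_ALPHA
) -> list[VariantRecord]:
    """Keep genome-wide significant associations (p strictly < threshold)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    return [r for r in records if r.pvalue < threshold]


#: Long-format columns of the serialized association matrix.
MATRIX_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "maf", "group", "pvalue"]


@dataclass
class AssociationMatrix:
    """Sparse record of significant (variant, group) associations.

    ``group`` is a trait id for the raw matrix and a cluster id after
    :func:`pleioscan.trait_clustering.assign_cluster_associations`.  One row
    per stored entry; every entry already passed the significance filter.
    """

    entries: pd.DataFrame
    unit: str = "trait"

    def __post_init__(self) -> None:
        missing = [c for c in MATRIX_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"association matrix is missing columns {missing}")
        self.entries = self.entries.reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        return sorted(self.entries["group"].unique())

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def variant_table(self) -> pd.DataFrame:
        """Deduplicated variant coordinates (one row per variant)."""
        return (
            self.entries[["variant_id", "chrom", "pos", "ref", "alt", "maf"]]
            .drop_duplicates("variant_id")
            .reset_index(drop=True)
        )

    def association_counts(self) -> pd.Series:
        """Number of associated groups per variant (variants with >= 1 entry)."""
        return self.entries.groupby("variant_id")["group"].nunique()

    def write(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, unit: str = "trait") -> "AssociationMatrix":
        df = pd.read_csv(
            path, sep="\t", dtype={"variant_id": str, "chrom": str, "ref": str, "alt": str, "group": str}
        )
        return cls(df, unit=unit)


def build_association_matrix(
    per_trait: Mapping[str, Sequence[VariantRecord]]
) -> AssociationMatrix:
    """Merge per-trait significant associations into one sparse matrix.

    Raises :class:`ConsistencyError` if the same variant id carries
    conflicting (chrom, pos, ref, alt) coordinates across traits.
    """
    seen: dict[str, tuple[str, int, str, str]] = {}
    rows = []
    for trait_id in sorted(per_trait):
        for r in per_trait[trait_id]:
            prev = seen.get(r.variant_id)
            if prev is None:
                seen[r.variant_id] = r.key
            elif prev != r.key:
                raise ConsistencyError(
                    f"variant {r.variant_id!r} has conflicting coordinates: {prev} vs {r.key}"
                )
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "chrom": normalize_chrom(r.chrom),
                    "pos": r.pos,
                    "ref": r.ref,
                    "alt": r.alt,
                    "maf": r.maf,
                    "group": trait_id,
                    "pvalue": r.pvalue,
                }
            )
    entries = pd.DataFrame(rows, columns=MATRIX_COLUMNS)
    return AssociationMatrix(entries, unit="trait")


def association_percentage(count: int, total: int) -> float:
    """Percentage of associated variants, 100*count/total to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 2)


def phenome_summary(
    matrix: AssociationMatrix, count_thresholds: Sequence[int] = (1, 5, 10)
) -> dict:
    """Summarize the association matrix over variants with >= 1 association.

    Returns total variant count, mean associations per variant, and for each
    threshold ``t`` the number and percentage (two decimals) of variants
    with strictly more than ``t`` associated groups.
    """
    if matrix.n_entries == 0:
        raise ValueError("no associations")
    counts = matrix.association_counts()
    total = int(len(counts))
    rows = []
    for t in count_thresholds:
        n = int((counts > t).sum())
        rows.append(
            {"threshold": int(t), "n_variants": n, "pct": association_percentage(n, total)}
        )
    return {
        "unit": matrix.unit,
        "total_variants": total,
        "mean_associations": float(counts.mean()),
        "thresholds": pd.DataFrame(rows, columns=["threshold", "n_variants", "pct"]),
    }
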