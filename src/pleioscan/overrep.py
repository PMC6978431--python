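"""Overrepresentation of variant annotation classes and genomic regions.

Hypergeometric comparison of annotation-class proportions between a
foreground variant set (e.g. pleiotropic variants) and the background it was
drawn from (e.g. all variants with at least one association): observing
k_fg flagged among n_fg foreground variants when the background holds k_bg
flagged among n_bg, the enrichment p-value is the upper tail
P(X >= k_fg), X ~ Hypergeometric(N=n_bg, K=k_bg, n=n_fg).  A two-sided
Fisher exact test is available behind a flag.

Annotation flags (cis-eQTL status, functional consequence classes, ...)
arrive as a data table — external annotators are not invoked.  eQTL p-value
columns are binarized at the conventional cis-eQTL significance of 5e-8.
A region-based variant tests whether query loci concentrate inside a region
of interest (e.g. MHC) relative to the locus universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .lsea import LocusInterval, LocusUniverse, Region, hypergeom_upper_tail

logger = logging.getLogger(__name__)

#: cis-eQTL significance threshold used to binarize eQTL p-value columns.
EQTL_ALPHA = 5e-8


@dataclass
class OverrepResult:
    """One flag's foreground-vs-background enrichment."""

    flag: str
    k_fg: int
    n_fg: int
    k_bg: int
    n_bg: int
    pvalue: float
    fisher_pvalue: float | None = None


def two_by_two_overrep(
    k_fg: int,
    n_fg: int,
    k_bg: int,
    n_bg: int,
    flag: str = "",
    two_sided_fisher: bool = False,
) -> OverrepResult:
    """Hypergeometric enrichment of a flag in a foreground subset.

    The foreground is treated as ``n_fg`` draws without replacement from a
    background population of ``n_bg`` containing ``k_bg`` flagged members;
    the p-value is P(X >= k_fg).  With ``two_sided_fisher`` the two-sided
    Fisher exact p of the foreground-vs-rest 2x2 table is also reported.
    """
    if not (0 <= k_fg <= n_fg and 0 <= k_bg <= n_bg):
        raise ValueError(f"inconsistent counts k_fg={k_fg} n_fg={n_fg} k_bg={k_bg} n_bg={n_bg}")
    if k_fg > k_bg or n_fg > n_bg:
        raise ValueError("foreground must be a subset of background (k_fg<=k_bg, n_fg<=n_bg)")
    p = hypergeom_upper_tail(k_fg, n_bg, k_bg, n_fg)
    fisher_p = None
    if two_sided_fisher:
        rest = [[k_fg, n_fg - k_fg], [k_bg - k_fg, (n_bg - n_fg) - (k_bg - k_fg)]]
        fisher_p = float(fisher_exact(rest, alternative="two-sided")[1])
    return OverrepResult(
        flag=flag, k_fg=int(k_fg), n_fg=int(n_fg), k_bg=int(k_bg), n_bg=int(n_bg),
        pvalue=p, fisher_pvalue=fisher_p,
    )


class AnnotationTable:
    """Per-variant annotation flags keyed by variant id.

    Columns may be boolean/0-1 flags, categorical labels (queried as
    ``"column=value"``), or p-value columns (floats in [0,1], binarized at
    the cis-eQTL threshold).  Variants missing from the table are treated as
    unflagged and logged.
    """

    def __init__(self, table: pd.DataFrame, key: str = "variant_id"):
        if key not in table.columns:
            raise ValueError(f"annotation table is missing key column {key!r}")
        df = table.copy()
        df[key] = df[key].astype(str)
        if df[key].duplicated().any():
            raise ValueError("annotation table must have one row per variant")
        self.table = df.set_index(key)

    @classmethod
    def read(cls, path: str | Path, key: str = "variant_id") -> "AnnotationTable":
        return cls(pd.read_csv(path, sep="\t"), key=key)

    def flag_values(
        self, flag: str, variants: Sequence[str], eqtl_alpha: float = EQTL_ALPHA
    ) -> np.ndarray:
        """Boolean flag status for ``variants`` (missing variants -> False)."""
        if "=" in flag:
            column, wanted = flag.split("=", 1)
        else:
            column, wanted = flag, None
        if column not in self.table.columns:
            raise ValueError(f"unknown flag {flag!r}")
        col = self.table[column].reindex(pd.Index([str(v) for v in variants]))
        n_missing = int(col.isna().sum())
        if n_missing:
            logger.warning(
                "%d variant(s) missing from annotation column %r treated as unflagged",
                n_missing, column,
            )
        if wanted is not None:
            return (col.astype("string") == wanted).fillna(False).to_numpy(dtype=bool)
        if pd.api.types.is_float_dtype(col):
            # p-value column: significant below the cis-eQTL threshold
            return (col < eqtl_alpha).fillna(False).to_numpy(dtype=bool)
        return col.map(lambda v: bool(v) if pd.notna(v) else False).to_numpy(dtype=bool)


def class_overrep(
    foreground: Sequence[str],
    background: Sequence[str],
    annotations: AnnotationTable,
    flags: Iterable[str],
    eqtl_alpha: float = EQTL_ALPHA,
    two_sided_fisher: bool = False,
) -> list[OverrepResult]:
    """Enrichment of each annotation flag in foreground vs background variants."""
    fg = [str(v) for v in foreground]
    bg = [str(v) for v in background]
    if not set(fg) <= set(bg):
        raise ValueError("foreground must be a subset of background")
    results = []
    for flag in flags:
        fg_hits = annotations.flag_values(flag, fg, eqtl_alpha=eqtl_alpha)
        bg_hits = annotations.flag_values(flag, bg, eqtl_alpha=eqtl_alpha)
        results.append(
            two_by_two_overrep(
                int(fg_hits.sum()), len(fg), int(bg_hits.sum()), len(bg),
                flag=flag, two_sided_fisher=two_sided_fisher,
            )
        )
    return results


def region_overrep(
    query: Sequence[LocusInterval],
    universe: LocusUniverse,
    region: Region,
    two_sided_fisher: bool = False,
) -> OverrepResult:
    """Overrepresentation of query loci inside a region of interest.

    The statistic is the number of query-hit universe intervals that overlap
    the region; the population is the universe, successes are universe
    intervals overlapping the region, and draws are the distinct universe
    intervals hit by the query.
    """
    region_hits = {
        i for i, iv in enumerate(universe.intervals)
        if region.overlaps(iv.chrom, iv.start, iv.end)
    }
    query_hits: set[int] = set()
    for iv in query:
        query_hits |= universe.hits(iv.chrom, iv.start, iv.end)
    k_fg = len(query_hits & region_hits)
    return two_by_two_overrep(
        k_fg, len(query_hits), len(region_hits), len(universe),
        flag=region.name or f"{region.chrom}:{region.start}-{region.end}",
        two_sided_fisher=two_sided_fisher,
    )


def overrep_table(results: Sequence[OverrepResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "flag": r.flag, "k_fg": r.k_fg, "n_fg": r.n_fg, "k_bg": r.k_bg,
                "n_bg": r.n_bg, "p": r.pvalue, "fisher_p": r.fisher_pvalue,
            }
            for r in results
        ],
        columns=["flag", "k_fg", "n_fg", "k_bg", "n_bg", "p", "fisher_p"],
    )
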