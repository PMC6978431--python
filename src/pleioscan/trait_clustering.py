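"""Trait clustering by phenotypic correlation and the cluster correlation matrix.

Many phenome entries are the same underlying phenotype in different encodings
or tightly correlated measurements; counting each as a separate association
grossly inflates apparent pleiotropy.  Traits are therefore grouped by
hierarchical clustering on the distance 1 - |corr(T_i, T_j)|, where corr is
the phenotypic correlation between traits (in the full-scale analysis a
summary-statistic reconstruction such as PhenoSpD provides this matrix; a
z-score correlation proxy over null variants is provided here for simulated
or fully-overlapping-sample data).  The number of clusters is chosen by mean
silhouette width.

Downstream, a variant is associated with a cluster if it is associated with
at least one member trait, and the correlation between two clusters is the
maximum absolute trait-pair correlation across the pair — the quantity the
pleiotropy score multiplies over cluster pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .gwas_io import MATRIX_COLUMNS, AssociationMatrix

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-8


class _SquareCorrelation:
    """Validated square correlation matrix keyed by string labels."""

    def __init__(self, values: pd.DataFrame):
        if list(values.index) != list(values.columns):
            raise ValueError("correlation matrix index and columns must match")
        arr = values.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=_SYM_TOL):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(arr).max() > 1.0 + _SYM_TOL:
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(arr), 1.0, atol=_SYM_TOL):
            raise ValueError("correlation matrix must have unit diagonal")
        self.values = values.astype(float)

    @property
    def labels(self) -> list[str]:
        return [str(t) for t in self.values.index]

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path):
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)


class TraitCorrelationMatrix(_SquareCorrelation):
    """Phenotypic correlation corr(T_i, T_j) between traits, in [-1, 1]."""

    @property
    def traits(self) -> list[str]:
        return self.labels


class ClusterCorrelationMatrix(_SquareCorrelation):
    """Cluster-pair correlation corr(C_n, C_m) = max member-pair |corr|, in [0, 1]."""

    @property
    def clusters(self) -> list[str]:
        return self.labels

    def pair(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])


def estimate_trait_correlation_proxy(
    zscores: pd.DataFrame, null_mask: np.ndarray | Sequence[bool] | None = None
) -> TraitCorrelationMatrix:
    """Estimate trait correlation as the correlation of null-variant z-scores.

    Under fully overlapping samples, association z-scores at variants with no
    true effect are correlated across traits exactly as the phenotypes are;
    the sample correlation over a large null set is therefore a proxy for the
    reconstructed phenotypic correlation.

    Parameters
    ----------
    zscores
        Variants x traits matrix of association z-scores.
    null_mask
        Boolean selector of null (no-effect) variants; all rows if omitted.
    """
    if zscores.shape[1] < 2:
        raise ValueError("at least 2 traits are required")
    sub = zscores if null_mask is None else zscores.loc[np.asarray(null_mask, dtype=bool)]
    if len(sub) < 30:
        raise ValueError(f"need >= 30 null variants, got {len(sub)}")
    corr = np.corrcoef(sub.to_numpy(dtype=float), rowvar=False)
    np.fill_diagonal(corr, 1.0)
    df = pd.DataFrame(corr, index=zscores.columns.astype(str), columns=zscores.columns.astype(str))
    return TraitCorrelationMatrix(df)


@dataclass
class TraitClustering:
    """A partition of traits into clusters with the silhouette scan that chose k."""

    labels: dict[str, str]  # trait_id -> cluster_id
    k: int
    silhouette_profile: dict[int, float]

    def __post_init__(self) -> None:
        if self.k != len(set(self.labels.values())):
            raise ValueError("k must equal the number of distinct cluster labels")

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for t, c in self.labels.items():
            out.setdefault(c, []).append(t)
        return {c: sorted(ts) for c, ts in out.items()}

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.labels.items()), columns=["trait_id", "cluster_id"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TraitClustering":
        df = pd.read_csv(path, sep="\t", dtype=str)
        labels = dict(zip(df["trait_id"], df["cluster_id"]))
        return cls(labels=labels, k=len(set(labels.values())), silhouette_profile={})


def _zero_distance_groups(dist: np.ndarray) -> list[list[int]]:
    """Connected components of the zero-distance graph (union of identical traits)."""
    n = dist.shape[0]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= 0.0:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def cluster_traits(
    corr: TraitCorrelationMatrix,
    linkage: str = "average",
    k_range: Sequence[int] | None = None,
) -> TraitClustering:
    """Hierarchically cluster traits on 1 - |corr| with silhouette-selected k.

    Agglomerative clustering (default average linkage) on the dissimilarity
    1 - |corr|; the tree is cut at every candidate k and the k maximizing the
    mean silhouette width is returned (ties broken toward smaller k).
    Zero-distance trait groups (|corr| = 1) are pre-merged before the scan so
    silhouettes are well defined; if the best mean silhouette is below 0.1 a
    warning is logged but the argmax k is still returned.
    """
    traits = corr.traits
    n = len(traits)
    if n < 3:
        raise ValueError("at least 3 traits are required for clustering")
    dist = 1.0 - np.abs(corr.values.to_numpy(dtype=float))
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)

    groups = _zero_distance_groups(dist)
    reps = [g[0] for g in groups]
    m = len(reps)
    if m < 2:
        raise ValueError("degenerate correlation structure: all traits identical")
    rdist = dist[np.ix_(reps, reps)]
    if m == 2:
        # Two distinct groups remain (e.g. two perfectly correlated pairs):
        # k = 2 is the only admissible cut and silhouettes are undefined.
        labels = {}
        for gi, g in enumerate(groups):
            for idx in g:
                labels[traits[idx]] = f"C{gi + 1}"
        return TraitClustering(labels=labels, k=2, silhouette_profile={})
    off = rdist[np.triu_indices(m, k=1)]
    if np.allclose(off, off[0]):
        raise ValueError("degenerate correlation structure: constant distances")

    if k_range is None:
        k_range = range(2, n)  # 2 .. n_traits - 1
    k_range = [k for k in k_range if 2 <= k <= m]
    if not k_range:
        raise ValueError("no feasible k in k_range after pre-merging identical traits")

    Z = scipy_linkage(squareform(rdist, checks=False), method=linkage)
    profile: dict[int, float] = {}
    cuts: dict[int, np.ndarray] = {}
    for k in k_range:
        lab = fcluster(Z, t=k, criterion="maxclust")
        realized = len(np.unique(lab))
        if realized < 2 or realized >= m:
            continue
        profile[k] = float(silhouette_score(rdist, lab, metric="precomputed"))
        cuts[k] = lab
    if not profile:
        raise ValueError("silhouette undefined for every candidate k")

    best_k = min(profile, key=lambda k: (-profile[k], k))
    if profile[best_k] < 0.1:
        logger.warning(
            "weak cluster structure: best mean silhouette %.3f at k=%d", profile[best_k], best_k
        )
    lab = cuts[best_k]

    # deterministic cluster ids, ordered by first trait appearance
    raw: dict[str, int] = {}
    for g, rep_lab in zip(groups, lab):
        for idx in g:
            raw[traits[idx]] = int(rep_lab)
    order: dict[int, str] = {}
    for t in traits:
        c = raw[t]
        if c not in order:
            order[c] = f"C{len(order) + 1}"
    labels = {t: order[raw[t]] for t in traits}
    return TraitClustering(labels=labels, k=len(order), silhouette_profile=profile)


def assign_cluster_associations(
    matrix: AssociationMatrix, clustering: TraitClustering
) -> AssociationMatrix:
    """Map the variant x trait matrix to variant x cluster.

    A variant is associated with a cluster if it is associated with at least
    one member trait; the entry keeps the smallest member p-value.
    """
    unknown = set(matrix.entries["group"]) - set(clustering.labels)
    if unknown:
        raise ValueError(f"trait(s) absent from clustering: {sorted(unknown)}")
    df = matrix.entries.copy()
    df["group"] = df["group"].map(clustering.labels)
    df = (
        df.sort_values("pvalue", kind="stable")
        .drop_duplicates(["variant_id", "group"], keep="first")
        .sort_values(["variant_id", "group"], kind="stable")
        .reset_index(drop=True)
    )
    return AssociationMatrix(df[MATRIX_COLUMNS], unit="cluster")


def cluster_pair_correlation(
    corr: TraitCorrelationMatrix, clustering: TraitClustering
) -> ClusterCorrelationMatrix:
    """corr(C_n, C_m) = max over T_i in C_n, T_j in C_m of |corr(T_i, T_j)|.

    The diagonal is set to 1 by definition and never enters pleiotropy-score
    products (which use unordered pairs n < m only).
    """
    members = clustering.members()
    clusters = sorted(members)
    abs_corr = corr.values.abs()
    out = pd.DataFrame(np.ones((len(clusters), len(clusters))), index=clusters, columns=clusters)
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            v = float(abs_corr.loc[members[a], members[b]].to_numpy().max())
            out.loc[a, b] = out.loc[b, a] = v
    return ClusterCorrelationMatrix(out)
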