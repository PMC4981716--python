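"""Coexpression clustering of a genes x conditions RPKM matrix.

Pipeline: remove genes in the bottom expression quantile, log2-transform and
z-score each gene across conditions, agglomerate with average-linkage
hierarchical clustering on Euclidean distances, cut the tree to k clusters,
and summarise each cluster by its eigengene — the first principal component
of the cluster's standardized profiles over conditions, with sign fixed to
correlate positively with the cluster mean profile.

The matrix convention throughout is a pandas DataFrame with gene identifiers
as the index and ordered condition labels (increasing irradiance) as columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class ClusterResult:
    """Gene cluster labels with per-cluster eigengenes."""

    labels: pd.Series  # gene id -> cluster id (1..k)
    k: int
    eigengenes: dict  # cluster id -> unit-norm profile over conditions
    variance_explained: dict  # cluster id -> fraction in (0, 1]
    conditions: list
    linkage_method: str = "average"
    metric: str = "euclidean"

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def filter_low_expression(matrix: pd.DataFrame, quantile: float = 0.20,
                          policy: str = "all"):
    """Drop genes in the bottom expression quantile.

    Per condition, the ``floor(quantile * n_genes)`` lowest-expressed genes
    form the bottom set (ties broken by gene identifier, ascending — stable
    and deterministic).  Under ``policy="all"`` a gene is removed only when
    it falls in the bottom set at *every* condition; under ``"any"``, at any
    condition.

    Returns ``(filtered_matrix, removed_gene_list)``.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if policy not in ("all", "any"):
        raise ValueError("policy must be 'all' or 'any'")
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("need at least 2 genes and 1 condition")
    n_bottom = math.floor(quantile * matrix.shape[0])
    in_bottom = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    order_ids = matrix.index.to_series()
    for cond in matrix.columns:
        ranked = matrix[cond].to_frame("v").assign(g=order_ids)
        ranked = ranked.sort_values(["v", "g"], kind="mergesort")
        bottom = ranked.index[:n_bottom]
        in_bottom.loc[bottom, cond] = True
    remove = in_bottom.all(axis=1) if policy == "all" else in_bottom.any(axis=1)
    removed = matrix.index[remove].tolist()
    return matrix.loc[~remove].copy(), removed


def transform_standardize(matrix: pd.DataFrame, pseudocount: float = 1.0):
    """log2(RPKM + pseudocount) then per-gene z-score (population sd).

    Genes constant across conditions (zero variance) cannot be standardized
    and are excluded; returns ``(standardized_matrix, excluded_gene_list)``.
    """
    if (matrix.values < 0).any():
        raise ValueError("RPKM values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    logged = np.log2(matrix + pseudocount)
    sd = logged.std(axis=1, ddof=0)
    constant = sd == 0
    excluded = matrix.index[constant].tolist()
    kept = logged.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return z, excluded


def cluster_genes(matrix: pd.DataFrame, k: int,
                  method: str = "average",
                  metric: str = "euclidean") -> ClusterResult:
    """Agglomerative hierarchical clustering of standardized profiles.

    The tree is cut to exactly ``k`` clusters.  Rows are processed in gene-
    identifier order so the result is deterministic regardless of input row
    order; cluster ids are renumbered 1..k by decreasing cluster size (ties
    by first gene id).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({matrix.shape[0]})")
    ordered = matrix.sort_index(kind="mergesort")
    Z = hierarchy.linkage(ordered.values, method=method, metric=metric)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=ordered.index, name="cluster")
    # canonical renumbering: by size desc, then by first member id
    groups = sorted(
        labels.groupby(labels).groups.items(),
        key=lambda kv: (-len(kv[1]), str(min(kv[1]))))
    remap = {old: new for new, (old, _) in enumerate(groups, start=1)}
    labels = labels.map(remap)
    eig, var = compute_eigengenes(ordered, labels)
    return ClusterResult(labels=labels.loc[matrix.index], k=int(labels.nunique()),
                         eigengenes=eig, variance_explained=var,
                         conditions=list(matrix.columns),
                         linkage_method=method, metric=metric)


def compute_eigengenes(matrix: pd.DataFrame, labels: pd.Series,
                       allow_singletons: bool = True):
    """First principal component per cluster over the condition axis.

    Each eigengene is the leading right singular vector of the cluster's
    genes x conditions submatrix: unit norm, sign chosen so it correlates
    non-negatively with the cluster's mean profile.  Variance explained is
    the leading squared singular value over the total.  A singleton cluster
    degenerates to the gene's own normalized profile (or raises when
    ``allow_singletons`` is False).

    Returns ``(eigengenes, variance_explained)`` keyed by cluster id.
    """
    eigengenes: dict = {}
    variance: dict = {}
    for cid, idx in labels.groupby(labels).groups.items():
        sub = matrix.loc[idx].values
        if sub.shape[0] < 2 and not allow_singletons:
            raise ValueError(f"cluster {cid} has fewer than 2 genes")
        _, s, vt = np.linalg.svd(sub, full_matrices=False)
        v = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        eigengenes[cid] = v
        total = float(np.sum(s ** 2))
        variance[cid] = float(s[0] ** 2 / total) if total > 0 else 0.0
    return eigengenes, variance


def correlate_eigengene(eigengene, phenotype) -> float:
    """Pearson correlation between an eigengene and a per-condition phenotype
    (e.g. growth rate)."""
    e = np.asarray(eigengene, dtype=float)
    p = np.asarray(phenotype, dtype=float)
    if e.shape != p.shape or e.size < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if np.ptp(e) == 0 or np.ptp(p) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(stats.pearsonr(e, p).statistic)


def merge_similar_clusters(result: ClusterResult, matrix: pd.DataFrame,
                           r_threshold: float = 0.8) -> ClusterResult:
    """Merge clusters whose eigengenes correlate above ``r_threshold``.

    Used to reduce a fine clustering (e.g. k=6) to its major modules: pairs
    of clusters with eigengene Pearson r > threshold are unioned
    transitively, then labels and eigengenes are recomputed.
    """
    ids = sorted(result.eigengenes)
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in ids:
        for b in ids:
            if a < b:
                r = float(np.corrcoef(result.eigengenes[a],
                                      result.eigengenes[b])[0, 1])
                if r > r_threshold:
                    parent[find(b)] = find(a)
    merged = result.labels.map(lambda c: find(c))
    # renumber 1..k' by size
    groups = sorted(merged.groupby(merged).groups.items(),
                    key=lambda kv: (-len(kv[1]), str(min(kv[1]))))
    remap = {old: new for new, (old, _) in enumerate(groups, start=1)}
    merged = merged.map(remap)
    ordered = matrix.sort_index(kind="mergesort")
    eig, var = compute_eigengenes(ordered, merged.loc[ordered.index])
    return ClusterResult(labels=merged, k=int(merged.nunique()),
                         eigengenes=eig, variance_explained=var,
                         conditions=result.conditions,
                         linkage_method=result.linkage_method,
                         metric=result.metric)


def cluster_pipeline(rpkm: pd.DataFrame, k: int = 6, quantile: float = 0.20,
                     policy: str = "all", pseudocount: float = 1.0,
                     n_major: int | None = 4,
                     merge_r_threshold: float = 0.8):
    """filter -> transform -> cluster -> (optionally) merge to major modules.

    Returns ``(ClusterResult, report_dict)`` where the report lists removed
    and excluded genes.  When ``n_major`` is set and merging by eigengene
    correlation leaves more clusters, the result of the merge is returned
    as-is (the merge criterion, not the count, is authoritative).
    """
    filtered, removed = filter_low_expression(rpkm, quantile, policy)
    z, excluded = transform_standardize(filtered, pseudocount)
    result = cluster_genes(z, k)
    report = {"removed_low_expression": removed,
              "excluded_constant": excluded,
              "k_initial": result.k}
    if n_major is not None and result.k > n_major:
        result = merge_similar_clusters(result, z, merge_r_threshold)
        report["k_after_merge"] = result.k
    return result, report
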