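"""Fisher exact functional-category enrichment per gene cluster.

For each (annotation level, category) represented in a cluster, a 2x2 table
is built over a gene universe — in-cluster vs out, in-category vs out — and
the one-sided (greater) Fisher exact test asks whether the category is over-
represented in the cluster.  Reported alongside the P value are the percent
of cluster genes carrying the category and the ratio of that percentage to
the category's percentage in the universe.

Annotation levels follow a three-tier functional hierarchy: main role,
subrole, subsystem.  A gene may carry several categories per level; each
category is tested independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

LEVELS = ("main_role", "subrole", "subsystem")


@dataclass(frozen=True)
class EnrichmentRow:
    """One (cluster, level, category) Fisher enrichment test."""

    cluster: object
    level: str
    category: str
    n_overlap: int
    n_cluster: int
    n_category: int
    n_universe: int
    pct_genes: float  # percent of cluster genes in the category
    ratio: float  # pct in cluster / pct in universe
    p_value: float  # one-sided (greater) Fisher exact
    significant: bool
    p_bh: float | None = None  # optional Benjamini-Hochberg adjusted P


class AnnotationMap:
    """gene -> set of (level, category) assignments."""

    def __init__(self, assignments: dict[str, set[tuple[str, str]]]):
        for gene, cats in assignments.items():
            for level, _ in cats:
                if level not in LEVELS:
                    raise ValueError(
                        f"gene {gene!r}: unknown annotation level {level!r}")
        self._map = {g: frozenset(c) for g, c in assignments.items()}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationMap":
        """Build from a (gene, level, category) long-format table."""
        required = {"gene", "level", "category"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        out: dict[str, set[tuple[str, str]]] = {}
        for gene, level, cat in df[["gene", "level", "category"]].itertuples(
                index=False):
            out.setdefault(str(gene), set()).add((str(level), str(cat)))
        return cls(out)

    def categories(self, gene: str) -> frozenset:
        return self._map.get(gene, frozenset())

    def genes_in(self, level: str, category: str, universe) -> set:
        return {g for g in universe if (level, category) in self.categories(g)}

    def __len__(self) -> int:
        return len(self._map)


def fisher_enrichment(cluster_genes, annotations: AnnotationMap,
                      universe_genes, alpha: float = 0.05,
                      levels=LEVELS, bh: bool = False) -> list[EnrichmentRow]:
    """One-sided Fisher enrichment of every category present in the cluster.

    ``cluster_genes`` must be a subset of ``universe_genes``.  Categories
    with no member in the universe are skipped.  Rows with raw P < ``alpha``
    are flagged significant; when ``bh`` is True a Benjamini-Hochberg
    adjusted P column is filled per level (the flag still uses the raw P).
    """
    cluster = set(map(str, cluster_genes))
    universe = set(map(str, universe_genes))
    if not cluster or not universe:
        raise ValueError("cluster and universe must be non-empty")
    if not cluster <= universe:
        raise ValueError("cluster genes must be a subset of the universe")

    # categories represented by at least one cluster gene, per level
    tested: dict[str, set[str]] = {lv: set() for lv in levels}
    for g in cluster:
        for level, cat in annotations.categories(g):
            if level in tested:
                tested[level].add(cat)

    rows: list[EnrichmentRow] = []
    for level in levels:
        for cat in sorted(tested[level]):
            in_cat = annotations.genes_in(level, cat, universe)
            K = len(in_cat)
            if K == 0:
                continue  # not represented in the universe: skipped
            k = len(in_cat & cluster)
            n_c = len(cluster)
            N = len(universe)
            table = [[k, n_c - k], [K - k, N - n_c - (K - k)]]
            p = float(stats.fisher_exact(table, alternative="greater")[1])
            pct = 100.0 * k / n_c
            ratio = (k / n_c) / (K / N)
            rows.append(EnrichmentRow(
                cluster=None, level=level, category=cat, n_overlap=k,
                n_cluster=n_c, n_category=K, n_universe=N,
                pct_genes=pct, ratio=ratio, p_value=p,
                significant=p < alpha))
    if bh and rows:
        rows = _add_bh(rows)
    return rows


def _add_bh(rows: list[EnrichmentRow]) -> list[EnrichmentRow]:
    """Benjamini-Hochberg adjusted P values, computed within each level."""
    from dataclasses import replace

    out = list(rows)
    for level in {r.level for r in rows}:
        idx = [i for i, r in enumerate(rows) if r.level == level]
        ps = [rows[i].p_value for i in idx]
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        adj = [0.0] * m
        prev = 1.0
        for rank_from_end, oi in enumerate(reversed(order)):
            rank = m - rank_from_end
            prev = min(prev, ps[oi] * m / rank)
            adj[oi] = prev
        for j, i in enumerate(idx):
            out[i] = replace(out[i], p_bh=adj[j])
    return out


def enrichment_table(cluster_result_labels: pd.Series,
                     annotations: AnnotationMap,
                     universe_genes=None, alpha: float = 0.05,
                     bh: bool = False) -> pd.DataFrame:
    """Enrichment rows for every cluster, as a tidy DataFrame.

    The default universe is the expressed (clustered) gene set; pass
    ``universe_genes`` explicitly to test against the whole annotated genome
    instead.
    """
    from dataclasses import replace

    if universe_genes is None:
        universe_genes = cluster_result_labels.index
    records = []
    for cid in sorted(cluster_result_labels.unique()):
        genes = cluster_result_labels.index[cluster_result_labels == cid]
        for row in fisher_enrichment(genes, annotations, universe_genes,
                                     alpha=alpha, bh=bh):
            records.append(replace(row, cluster=cid).__dict__)
    return pd.DataFrame(records)
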