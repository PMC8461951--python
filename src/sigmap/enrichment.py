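"""Gene-set over-representation of signatures and co-expression clusters.

The overlap of a query gene list with each set in a GMT collection is
tested with the upper-tail hypergeometric distribution: with a universe
of N genes of which K are in the set, and a query of n genes overlapping
the set in k, p = P[X >= k] for X ~ Hypergeometric(N, K, n).  p-values
are Benjamini-Hochberg adjusted across all sets in the collection.
Ranked running-sum enrichment is deliberately not implemented: the use
case is plain gene lists against curated collections.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError
from .io_formats import AnnotationMap, GeneSetCollection

__all__ = ["overrepresentation", "enrich_clusters"]

RESULT_COLUMNS = [
    "set_name",
    "universe_size",
    "set_size",
    "query_size",
    "overlap",
    "p",
    "p_adj",
    "overlap_genes",
]


def overrepresentation(
    query, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    ``universe`` must contain every query gene; set members outside the
    universe are dropped before testing (the declared handling of
    set/universe mismatch).  Returns one row per set, ranked by p then
    name, with BH-adjusted p across the whole collection.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValidationError("empty query")
    if not universe:
        raise ValidationError("empty universe")
    stray = query - universe
    if stray:
        raise ValidationError(f"query genes outside the universe: {sorted(stray)[:10]}")
    N = len(universe)
    n = len(query)
    rows = []
    for name in collection.names():
        members = collection[name] & universe
        K = len(members)
        overlap = query & members
        k = len(overlap)
        # upper tail including k itself; k=0 gives p=1 exactly
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "universe_size": N,
                "set_size": K,
                "query_size": n,
                "overlap": k,
                "p": min(p, 1.0),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table[RESULT_COLUMNS].sort_values(["p", "set_name"], kind="stable")
    return table.reset_index(drop=True)


def enrich_clusters(
    clusters: pd.Series,
    collection: GeneSetCollection,
    universe,
    annotation: AnnotationMap | None = None,
    min_size: int = 5,
) -> dict[int, pd.DataFrame]:
    """Over-representation per co-expression cluster.

    Probe-set cluster members are translated to gene symbols via the
    annotation (duplicates collapsed); clusters with fewer than
    ``min_size`` genes are skipped with a warning.  Raises if no cluster
    qualifies.
    """
    results: dict[int, pd.DataFrame] = {}
    for c in sorted(clusters.unique()):
        members = clusters.index[clusters == c].tolist()
        genes = annotation.genes_for(members) if annotation is not None else list(dict.fromkeys(members))
        genes = [g for g in genes if g in set(universe)]
        if len(genes) < min_size:
            warnings.warn(f"cluster {c}: only {len(genes)} mapped genes (< {min_size}); skipped")
            continue
        results[c] = overrepresentation(genes, collection, universe)
    if not results:
        raise ValidationError(f"no cluster has >= {min_size} mapped genes in the universe")
    return results
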