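"""Regulon-to-pathway enrichment with redundancy collapse.

Each regulon is compared with each pathway gene set by Jaccard similarity,
with an exact hypergeometric upper-tail p-value on the overlap; terms are
BH-adjusted within a regulon.  Because pathway collections are heavily
redundant, enriched terms are clustered (average linkage on 1 - Jaccard)
and each cluster is represented by its smallest-p term.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datamodel import RegulonSet

__all__ = ["jaccard_test", "enrich_regulons", "collapse_terms"]


def jaccard_test(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[float, int, float]:
    """Jaccard index, overlap size and hypergeometric tail p.

    p is the probability of drawing at least the observed overlap when
    |A| genes are sampled from the universe containing |B| successes.
    """
    if len(universe) < 10:
        raise ValueError("universe must contain at least 10 genes")
    a = set_a & universe
    b = set_b & universe
    if not a or not b:
        return 0.0, 0, 1.0
    overlap = len(a & b)
    jac = overlap / len(a | b)
    # P(X >= overlap), X ~ Hypergeom(N=|U|, K=|B|, n=|A|)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(b), len(a)))
    return jac, overlap, min(p, 1.0)


def enrich_regulons(
    regulons: RegulonSet,
    gene_sets: dict[str, list[str]],
    universe: set[str],
    min_size: int = 10,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Jaccard test of every regulon against every size-filtered term.

    Terms are intersected with the universe (the measured genes) first and
    kept only when the intersection holds between ``min_size`` and
    ``max_size`` genes inclusive.  p-values are BH-adjusted across terms
    within each regulon.
    """
    filtered = {}
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        if min_size <= len(members) <= max_size:
            filtered[name] = members
    if not filtered:
        warnings.warn("no gene set survives the size filter", stacklevel=2)
        return pd.DataFrame(
            columns=["regulon", "term", "jaccard", "overlap", "p", "p_adj"]
        )
    rows = []
    for tf, targets in regulons:
        reg_genes = {t for t, _ in targets} & universe
        for term in sorted(filtered):
            jac, ov, p = jaccard_test(reg_genes, filtered[term], universe)
            rows.append((tf, term, jac, ov, p))
    df = pd.DataFrame(rows, columns=["regulon", "term", "jaccard", "overlap", "p"])
    df["p_adj"] = df.groupby("regulon")["p"].transform(
        lambda ps: stats.false_discovery_control(ps, method="bh")
    )
    return df


def collapse_terms(
    table: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    cut: float = 0.7,
) -> pd.DataFrame:
    """Cluster enriched terms by gene-set overlap and mark representatives.

    Pairwise distance is 1 - Jaccard between term gene sets; average-linkage
    clusters are cut at ``cut`` and the smallest-p term in each cluster
    (ties on term id) becomes its representative.  Adds ``cluster`` and
    ``is_representative`` columns.
    """
    if table.empty:
        raise ValueError("no enriched terms to collapse")
    terms = sorted(table["term"].unique())
    sets = {t: set(gene_sets[t]) for t in terms}
    n = len(terms)
    if n == 1:
        out = table.copy()
        out["cluster"] = 1
        out["is_representative"] = True
        return out
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[terms[i]], sets[terms[j]]
            union = len(a | b)
            jac = len(a & b) / union if union else 0.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    linkage = hierarchy.average(squareform(dist, checks=False))
    assignment = hierarchy.fcluster(linkage, t=cut, criterion="distance")
    cluster_of = dict(zip(terms, assignment))
    out = table.copy()
    out["cluster"] = out["term"].map(cluster_of)
    # representative = min p in cluster, ties to the smaller term id
    out["is_representative"] = False
    for _, grp in out.groupby("cluster"):
        best = grp.sort_values(["p", "term"]).index[0]
        out.loc[best, "is_representative"] = True
    return out
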