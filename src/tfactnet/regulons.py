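"""Regulon calling: normal-fit truncation plus preranked GSEA leading edge.

For each TF the integrated network's target weights are modeled as a
normal distribution; only targets beyond the upper q-quantile survive
(q = 0.01 by default, i.e. mean + 2.33 sd).  The survivors are then tested
as a gene set against the expression-derived GRN ranking with a classic
weighted Kolmogorov-Smirnov running sum, and the leading edge — the members
at or before the running-sum maximum — becomes the TF's positively
regulated target set.  Likelihood weights are the integrated weights
rescaled to (0, 1] within each regulon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import RegulonSet, WeightedEdgeList

__all__ = ["GseaResult", "truncate_targets", "preranked_gsea", "call_regulons"]


@dataclass
class GseaResult:
    es: float
    p: float
    leading_edge: list[str]
    nperm_used: int


def truncate_targets(
    tf_edges: list[tuple[str, float]],
    q: float = 0.01,
    min_regulon_size: int = 10,
) -> list[str]:
    """Keep targets whose weight exceeds the fitted-normal upper q tail.

    The threshold is mean + z_(1-q) * sd with the maximum-likelihood
    (population) sd.  Degenerate cases — fewer than 3 targets, constant
    weights, or fewer than ``min_regulon_size`` survivors — fall back to
    the top ``min_regulon_size`` targets by weight (ties on target id).
    """
    if not (0.0 < q < 0.5):
        raise ValueError("q must lie in (0, 0.5)")
    if len(tf_edges) < 3:
        return [t for t, _ in tf_edges]

    def top_n(n: int) -> list[str]:
        ranked = sorted(tf_edges, key=lambda tw: (-tw[1], tw[0]))
        return [t for t, _ in ranked[:n]]

    weights = np.array([w for _, w in tf_edges], dtype=float)
    mu = weights.mean()
    sigma = weights.std()
    if sigma == 0.0:
        return top_n(min_regulon_size)
    threshold = mu + stats.norm.ppf(1.0 - q) * sigma
    kept = [t for t, w in tf_edges if w > threshold]
    if len(kept) < min_regulon_size:
        return top_n(min_regulon_size)
    return kept


def _running_es(order_stats: np.ndarray, member_mask: np.ndarray) -> tuple[float, int]:
    """Signed max deviation of the weighted KS running sum and its argmax.

    ``order_stats`` are |stat| in ranking order; in-set positions step up
    proportionally to their |stat| (equal steps when all member stats are
    zero), out-of-set positions step down uniformly.
    """
    n = len(order_stats)
    n_in = int(member_mask.sum())
    if n_in == 0 or n_in == n:
        return 0.0, -1
    hit_w = np.where(member_mask, order_stats, 0.0)
    total = hit_w.sum()
    if total > 0:
        hits = np.cumsum(hit_w) / total
    else:  # all member stats zero: unweighted steps
        hits = np.cumsum(member_mask.astype(float)) / n_in
    misses = np.cumsum(~member_mask) / (n - n_in)
    diff = hits - misses
    i_max = int(np.argmax(np.abs(diff)))
    return float(diff[i_max]), i_max


def preranked_gsea(
    ranked: list[tuple[str, float]],
    gene_set: list[str],
    nperm: int = 1000,
    seed: int | None = None,
) -> GseaResult:
    """Weighted-KS enrichment of a gene set in a ranked list.

    Genes are sorted by statistic descending (ties on id); ES is the signed
    maximum running-sum deviation with exponent-1 weights on |stat|.  The
    leading edge contains the set members at or before the maximum of the
    positive deviation (empty when ES <= 0).  The p-value is Monte-Carlo:
    random same-size gene sets, add-one corrected.
    """
    if nperm < 100:
        warnings.warn("nperm < 100 gives a very coarse p-value", stacklevel=2)
    order = sorted(ranked, key=lambda gs: (-gs[1], gs[0]))
    genes = [g for g, _ in order]
    stats_abs = np.abs(np.array([s for _, s in order], dtype=float))
    members = set(gene_set)
    mask = np.array([g in members for g in genes])
    n_in = int(mask.sum())
    if n_in == 0:
        raise ValueError("gene set does not intersect the ranked list")
    es, i_max = _running_es(stats_abs, mask)
    if es > 0:
        leading = [g for g, m in zip(genes[: i_max + 1], mask[: i_max + 1]) if m]
    else:
        leading = []

    rng = np.random.default_rng(seed)
    n = len(genes)
    null_es = np.empty(nperm)
    for b in range(nperm):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(n, size=n_in, replace=False)] = True
        null_es[b], _ = _running_es(stats_abs, perm_mask)
    p = (1.0 + float((null_es >= es).sum())) / (1.0 + nperm)
    return GseaResult(es=es, p=p, leading_edge=leading, nperm_used=nperm)


def call_regulons(
    net: WeightedEdgeList,
    grn: WeightedEdgeList,
    q: float = 0.01,
    nperm: int = 1000,
    seed: int | None = None,
    min_regulon_size: int = 10,
    p_max: float = 1.0,
) -> RegulonSet:
    """Regulons from the integrated network refined by the GRN ranking.

    Per TF: normal-fit truncation of its integrated targets, then the
    leading edge of that list against the GRN weights of the TF over all
    genes (genes the GRN never scored get statistic 0 and rank last).  TFs
    without any GRN row keep the truncated list unrefined.  Regulons below
    ``min_regulon_size`` are topped up with the strongest truncated targets.
    """
    grn_by_tf: dict[str, dict[str, float]] = {}
    for r, t, w in grn.edges:
        grn_by_tf.setdefault(r, {})[t] = w
    all_genes = sorted(
        {t for _, t, _ in grn.edges} | {r for r, _, _ in grn.edges}
        | {t for _, t, _ in net.edges}
    )
    net_by_tf: dict[str, list[tuple[str, float]]] = {}
    for r, t, w in net.edges:
        net_by_tf.setdefault(r, []).append((t, w))

    regulons: dict[str, list[tuple[str, float]]] = {}
    for idx, tf in enumerate(sorted(net_by_tf)):
        tf_edges = net_by_tf[tf]
        truncated = truncate_targets(tf_edges, q=q, min_regulon_size=min_regulon_size)
        wmap = dict(tf_edges)
        grn_row = grn_by_tf.get(tf)
        if grn_row is None:
            warnings.warn(f"TF {tf!r} has no GRN row; regulon not GSEA-refined",
                          stacklevel=2)
            members = list(truncated)
        else:
            ranked = [(g, grn_row.get(g, 0.0)) for g in all_genes if g != tf]
            result = preranked_gsea(
                ranked, truncated, nperm=nperm,
                seed=None if seed is None else seed + idx,
            )
            members = list(result.leading_edge) if result.p <= p_max else []
        if len(members) < min_regulon_size:
            extra = [t for t in sorted(truncated, key=lambda t: (-wmap[t], t))
                     if t not in members]
            members.extend(extra[: min_regulon_size - len(members)])
        if not members:
            continue
        w = np.array([wmap[t] for t in members], dtype=float)
        lik = w / w.max() if w.max() > 0 else np.ones_like(w)
        regulons[tf] = [(t, float(l)) for t, l in zip(members, lik)]
    return RegulonSet(regulons)
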