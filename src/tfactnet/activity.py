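"""Per-cell TF activity from regulons.

Three interchangeable rank-based engines score how strongly a regulon's
targets concentrate at the top of each cell's expression ranking:

* ``area_activity`` (default) — analytic rank-based enrichment: ranks are
  mapped through the standard-normal quantile function and averaged with
  the regulon's likelihood weights, normalized so random ranks give
  N(0, 1) scores.
* ``ssgsea_activity`` — single-sample GSEA: the area between the weighted
  in-set and uniform out-of-set cumulative curves.
* ``aucell_activity`` — area under the recovery curve within the top
  fraction of the ranking.

All three depend on the expression values only through per-cell ranks, so
any strictly increasing per-cell transformation leaves them unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .datamodel import ActivityMatrix, GeneExpressionMatrix, RegulonSet

__all__ = ["area_activity", "ssgsea_activity", "aucell_activity", "compute_activity"]


def _regulon_indices(
    expr: GeneExpressionMatrix, regulons: RegulonSet
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per TF: indices of regulon members present in the matrix + weights."""
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    out = {}
    for tf, targets in regulons:
        idx, w = [], []
        for t, lik in targets:
            if t in pos:
                idx.append(pos[t])
                w.append(lik)
        if not idx:
            warnings.warn(f"regulon {tf!r} has no measured member; activity is NaN",
                          stacklevel=3)
            out[tf] = (np.array([], dtype=int), np.array([]))
        else:
            out[tf] = (np.array(idx, dtype=int), np.array(w, dtype=float))
    return out


def area_activity(expr: GeneExpressionMatrix, regulons: RegulonSet) -> ActivityMatrix:
    """Weighted normal-quantile rank enrichment (one-tailed).

    Per cell, gene ranks (1 = lowest, average ties) become quantiles
    t = rank/(n+1) and normal scores q = Phi^-1(t); a regulon with
    likelihood weights w scores NES = sum(w q) / sqrt(sum(w^2)), which is
    standard normal when ranks are exchangeable.
    """
    n = expr.n_genes
    if n < 2:
        raise ValueError("need at least 2 genes")
    ranks = np.apply_along_axis(stats.rankdata, 0, expr.lognorm)
    qnorm = stats.norm.ppf(ranks / (n + 1))
    reg_idx = _regulon_indices(expr, regulons)
    tf_ids = sorted(reg_idx)
    scores = np.full((len(tf_ids), expr.n_cells), np.nan)
    for i, tf in enumerate(tf_ids):
        idx, w = reg_idx[tf]
        if idx.size == 0:
            continue
        scores[i] = w @ qnorm[idx] / np.sqrt((w**2).sum())
    return ActivityMatrix(scores, tf_ids, list(expr.cell_ids))


def ssgsea_activity(
    expr: GeneExpressionMatrix,
    regulons: RegulonSet,
    alpha: float = 0.25,
    normalize: bool = False,
) -> ActivityMatrix:
    """Single-sample GSEA score per regulon and cell.

    Genes are sorted by expression descending; in-set genes step the hit
    curve up proportionally to (descending-rank value)^alpha, out-of-set
    genes step the miss curve up uniformly, and the score is the sum of the
    running difference over all positions.  ``normalize`` min-max scales
    each TF's scores across cells.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    n = expr.n_genes
    reg_idx = _regulon_indices(expr, regulons)
    tf_ids = sorted(reg_idx)
    scores = np.full((len(tf_ids), expr.n_cells), np.nan)
    rank_values = np.arange(n, 0, -1, dtype=float) ** alpha  # position 0 = top
    for c in range(expr.n_cells):
        order = np.argsort(-expr.lognorm[:, c], kind="stable")
        in_order_pos = np.empty(n, dtype=int)
        in_order_pos[order] = np.arange(n)
        for i, tf in enumerate(tf_ids):
            idx, _ = reg_idx[tf]
            if idx.size == 0 or idx.size == n:
                if idx.size == n:
                    scores[i, c] = 0.0
                continue
            mask = np.zeros(n, dtype=bool)
            mask[in_order_pos[idx]] = True
            hit_w = np.where(mask, rank_values, 0.0)
            hits = np.cumsum(hit_w) / hit_w.sum()
            misses = np.cumsum(~mask) / (n - idx.size)
            scores[i, c] = float((hits - misses).sum())
    if normalize:
        for i in range(len(tf_ids)):
            row = scores[i]
            lo, hi = np.nanmin(row), np.nanmax(row)
            if hi > lo:
                scores[i] = (row - lo) / (hi - lo)
    return ActivityMatrix(scores, tf_ids, list(expr.cell_ids))


def aucell_activity(
    expr: GeneExpressionMatrix,
    regulons: RegulonSet,
    top_frac: float = 0.05,
) -> ActivityMatrix:
    """Area under the regulon recovery curve in the top-ranked genes.

    Per cell the top K = ceil(top_frac * n) genes are scanned; the curve
    r(k) counts regulon members among the top k and the score is
    sum_k r(k) / (K * |regulon|), in [0, 1].
    """
    if not (0.0 < top_frac <= 1.0):
        raise ValueError("top_frac must lie in (0, 1]")
    n = expr.n_genes
    k_top = int(np.ceil(top_frac * n))
    reg_idx = _regulon_indices(expr, regulons)
    tf_ids = sorted(reg_idx)
    scores = np.full((len(tf_ids), expr.n_cells), np.nan)
    for c in range(expr.n_cells):
        order = np.argsort(-expr.lognorm[:, c], kind="stable")
        pos_of = np.empty(n, dtype=int)
        pos_of[order] = np.arange(n)
        for i, tf in enumerate(tf_ids):
            idx, _ = reg_idx[tf]
            if idx.size == 0:
                continue
            positions = pos_of[idx]
            hits = np.zeros(k_top)
            inside = positions[positions < k_top]
            if inside.size:
                counts = np.bincount(inside, minlength=k_top)
                hits = np.cumsum(counts)
            scores[i, c] = float(hits.sum() / (k_top * idx.size))
    return ActivityMatrix(scores, tf_ids, list(expr.cell_ids))


def compute_activity(
    expr: GeneExpressionMatrix,
    regulons: RegulonSet,
    method: str = "area",
    **kwargs,
) -> ActivityMatrix:
    """Dispatch to one of the three engines by name."""
    engines = {
        "area": area_activity,
        "ssgsea": ssgsea_activity,
        "aucell": aucell_activity,
    }
    if method not in engines:
        raise ValueError(f"unknown activity method {method!r}")
    return engines[method](expr, regulons, **kwargs)
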