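"""Perturbation benchmark harness.

Pooled CRISPR screens give ground truth for TF activity: in a successful
knockout arm the TF's regulatory output should drop relative to control
cells.  This module QCs the perturbation arms (the targeted TF must itself
be significantly downregulated), scores each TF's activity row by AUROC
between control and perturbed cells, and provides the random-zeroing
dropout corruption used to probe robustness.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ActivityMatrix,
    GeneExpressionMatrix,
    PerturbationDesign,
)

__all__ = ["qc_perturbed_arms", "auroc", "benchmark_activity", "simulate_dropout"]


def qc_perturbed_arms(
    expr: GeneExpressionMatrix,
    design: PerturbationDesign,
    p_max: float = 0.05,
    logfc_max: float = -1.0,
    min_cells: int = 10,
) -> PerturbationDesign:
    """Keep only arms whose perturbation verifiably worked.

    An arm survives when it has at least ``min_cells`` cells and a Welch
    t-test of the targeted TF's log-normalized expression against control
    cells shows p < ``p_max`` with log fold change below ``logfc_max``
    (knockout) or above ``-logfc_max`` (overexpression).  logFC is the
    difference of mean log2-normalized expression.
    """
    control_cells = design.cells_in(design.control_arm)
    if not control_cells:
        raise ValueError("control arm has no cells")
    cell_pos = {c: i for i, c in enumerate(expr.cell_ids)}
    ctrl_idx = np.array([cell_pos[c] for c in control_cells if c in cell_pos])
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}

    kept_arms: dict[str, tuple[str | None, str]] = {
        design.control_arm: design.arms[design.control_arm]
    }
    for arm in design.perturbed_arms():
        tf, direction = design.arms[arm]
        if tf not in gene_pos:
            warnings.warn(f"arm {arm!r}: TF {tf!r} absent from matrix; dropped",
                          stacklevel=2)
            continue
        cells = [c for c in design.cells_in(arm) if c in cell_pos]
        if len(cells) < min_cells:
            continue
        idx = np.array([cell_pos[c] for c in cells])
        x = expr.lognorm[gene_pos[tf], idx]
        y = expr.lognorm[gene_pos[tf], ctrl_idx]
        _, p = stats.ttest_ind(x, y, equal_var=False)
        logfc = float(x.mean() - y.mean())
        if direction == "knockout":
            ok = p < p_max and logfc < logfc_max
        else:  # overexpression: the TF must be up instead
            ok = p < p_max and logfc > -logfc_max
        if ok:
            kept_arms[arm] = (tf, direction)
    arm_of = {c: a for c, a in design.arm_of.items() if a in kept_arms}
    return PerturbationDesign(arm_of, kept_arms)


def auroc(scores: np.ndarray, positive_mask: np.ndarray) -> float:
    """Rank-sum AUROC with ties counting one half.

    Equivalent to the probability that a random positive outscores a random
    negative, with ties split evenly (Mann-Whitney U / (n_pos * n_neg)).
    """
    scores = np.asarray(scores, dtype=float)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    n_pos = int(positive_mask.sum())
    n_neg = int((~positive_mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    u = ranks[positive_mask].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def benchmark_activity(
    act: ActivityMatrix, design: PerturbationDesign
) -> pd.DataFrame:
    """Per-TF AUROC of activity between control and perturbed cells.

    For knockouts control cells are the positive class (activity should be
    higher there); for overexpression the labels flip.  Each arm is scored
    against the control cells only, on the cells present in the activity
    matrix.
    """
    cell_pos = {c: i for i, c in enumerate(act.cell_ids)}
    ctrl = [c for c in design.cells_in(design.control_arm) if c in cell_pos]
    rows = []
    for arm in design.perturbed_arms():
        tf, direction = design.arms[arm]
        if tf not in act.tf_ids:
            warnings.warn(f"TF {tf!r} missing from activity matrix; skipped",
                          stacklevel=2)
            continue
        perturbed = [c for c in design.cells_in(arm) if c in cell_pos]
        if not perturbed or not ctrl:
            continue
        cells = ctrl + perturbed
        scores = act.row(tf)[[cell_pos[c] for c in cells]]
        positive = np.array([True] * len(ctrl) + [False] * len(perturbed))
        if direction == "overexpression":
            positive = ~positive
        rows.append((tf, auroc(scores, positive),
                     int(positive.sum()), int((~positive).sum())))
    return pd.DataFrame(rows, columns=["tf", "auroc", "n_pos", "n_neg"])


def simulate_dropout(
    expr: GeneExpressionMatrix, ratio: float, seed: int | None = None
) -> GeneExpressionMatrix:
    """Zero a uniform random fraction of all matrix positions.

    Exactly ``floor(ratio * n_genes * n_cells)`` positions (drawn without
    replacement over the whole matrix, so already-zero entries count too)
    are set to zero and the log-normalized layer is recomputed.
    """
    if not (0.0 <= ratio < 1.0):
        raise ValueError("ratio must lie in [0, 1)")
    if ratio == 0.0:
        return expr
    rng = np.random.default_rng(seed)
    total = expr.n_genes * expr.n_cells
    n_zero = int(np.floor(ratio * total))
    flat_idx = rng.choice(total, size=n_zero, replace=False)
    values = expr.values.copy()
    values.ravel()[flat_idx] = 0.0
    return GeneExpressionMatrix(
        values, list(expr.gene_ids), list(expr.cell_ids),
        lognorm_target=expr.lognorm_target,
    )
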