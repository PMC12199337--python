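"""Cell-type specificity of TF activity via Jensen-Shannon divergence.

A TF's activity profile over cells, min-max scaled and normalized to a
probability vector, is compared with the idealized pattern in which the TF
is active only in one cell type (uniform over that type's cells).  The
cell-type-specific score is

    CSS = 1 - sqrt(JSD(r, r_c))        (JSD in bits, so CSS is in [0, 1])

with significance from shuffling the cell labels: the p-value is the
fraction of shuffled CSS values exceeding the observed one, adjusted
across all (TF, type) pairs with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ActivityMatrix, CellAnnotation

__all__ = ["jsd", "css", "css_bootstrap_p", "find_all_cts_regulons"]


def _h_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def jsd(g: np.ndarray, g2: np.ndarray) -> float:
    """Jensen-Shannon divergence of two probability vectors, in bits."""
    g = np.asarray(g, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g.shape != g2.shape:
        raise ValueError("vectors must have equal length")
    for v in (g, g2):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
            raise ValueError("inputs must be probability vectors")
    return _h_bits((g + g2) / 2.0) - 0.5 * (_h_bits(g) + _h_bits(g2))


def _activity_prob(activity: np.ndarray) -> np.ndarray:
    """Min-max scale then normalize to sum 1; constant input -> uniform."""
    a = np.asarray(activity, dtype=float)
    lo, hi = a.min(), a.max()
    if hi > lo:
        a = (a - lo) / (hi - lo)
    else:
        a = np.ones_like(a)
    s = a.sum()
    if s == 0:  # all cells at the minimum: no preference, use uniform
        return np.full(a.shape, 1.0 / a.size)
    return a / s


def css(activity: np.ndarray, labels: np.ndarray, cell_type: str) -> float:
    """CSS of one TF's activity vector for one cell type.

    ``labels`` is the per-cell type vector aligned with ``activity``.
    Positive affine changes of the activity cancel in the min-max step.
    """
    labels = np.asarray(labels)
    mask = labels == cell_type
    if not mask.any():
        raise ValueError(f"cell type {cell_type!r} not present")
    if activity.size < 2:
        raise ValueError("need at least 2 cells")
    r = _activity_prob(activity)
    rc = mask.astype(float) / mask.sum()
    return 1.0 - float(np.sqrt(jsd(r, rc)))


def _css_from_subsets(r: np.ndarray, subset_idx: np.ndarray, n_c: int) -> np.ndarray:
    """CSS for many candidate cell subsets at once.

    ``subset_idx`` is (n_boot, n_c) cell indices.  Uses the decomposition
    H(mix) = sum(term0) + sum_S(term1 - term0) where term0/term1 are the
    entropy contributions of r_i/2 with and without the indicator mass.
    """
    u = 1.0 / n_c

    def h_term(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = -x[nz] * np.log2(x[nz])
        return out

    term0 = h_term(r / 2.0)
    term1 = h_term((r + u) / 2.0)
    dterm = term1 - term0
    h_mix = term0.sum() + dterm[subset_idx].sum(axis=1)
    jsd_vals = np.clip(h_mix - 0.5 * (_h_bits(r) + np.log2(n_c)), 0.0, None)
    return 1.0 - np.sqrt(jsd_vals)


def css_bootstrap_p(
    activity: np.ndarray,
    labels: np.ndarray,
    cell_type: str,
    n_boot: int = 10_000,
    seed: int | None = None,
    add_one: bool = False,
) -> float:
    """Label-shuffle p-value: fraction of shuffled CSS above the observed.

    With ``add_one`` the (1 + x) / (1 + n) correction keeps p > 0; off by
    default so the raw shuffle fraction is reported.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    labels = np.asarray(labels)
    mask = labels == cell_type
    n_c = int(mask.sum())
    if n_c == 0:
        raise ValueError(f"cell type {cell_type!r} not present")
    observed = css(activity, labels, cell_type)
    r = _activity_prob(activity)
    rng = np.random.default_rng(seed)
    m = r.size
    sims = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e7 // max(m, 1))))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        # b independent label shuffles = b uniform size-n_c subsets
        idx = np.argsort(rng.random((b, m)), axis=1)[:, :n_c]
        sims[done : done + b] = _css_from_subsets(r, idx, n_c)
        done += b
    exceed = int((sims > observed).sum())
    if add_one:
        return (1 + exceed) / (1 + n_boot)
    return exceed / n_boot


def find_all_cts_regulons(
    act: ActivityMatrix,
    labels: CellAnnotation,
    css_min: float = 0.3,
    padj_max: float = 0.05,
    percent_min: float = 0.1,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """CSS, shuffle p, BH-adjusted p and detection percent per (TF, type).

    ``percent`` is the fraction of the type's cells whose activity exceeds
    the TF's across-cell median.  Rows passing all three thresholds get
    ``significant = True``.  TFs with undefined (NaN) activity are skipped.
    """
    lab = labels.for_cells(act.cell_ids)
    types = sorted(set(lab))
    if len(types) < 2:
        warnings.warn("single cell type: specificity is not meaningful", stacklevel=2)
    rows = []
    for i, tf in enumerate(act.tf_ids):
        a = act.scores[i]
        if not np.all(np.isfinite(a)):
            warnings.warn(f"TF {tf!r} has undefined activity; skipped", stacklevel=2)
            continue
        median = np.median(a)
        for j, ct in enumerate(types):
            mask = lab == ct
            score = css(a, lab, ct)
            p = css_bootstrap_p(
                a, lab, ct, n_boot=n_boot,
                seed=None if seed is None else seed + i * len(types) + j,
            )
            percent = float((a[mask] > median).mean())
            rows.append((tf, ct, score, p, percent))
    df = pd.DataFrame(rows, columns=["tf", "cell_type", "css", "p", "percent"])
    if len(df):
        df["p_adj"] = stats.false_discovery_control(df["p"], method="bh")
        df["significant"] = (
            (df["css"] > css_min) & (df["p_adj"] < padj_max) & (df["percent"] > percent_min)
        )
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df[["tf", "cell_type", "css", "p", "p_adj", "percent", "significant"]]
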