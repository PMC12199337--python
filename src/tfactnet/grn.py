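"""Entropy-based GRN inference via partial information decomposition.

For every ordered regulator-target pair (R, T) the mutual information
I(R;T) is decomposed, against every third gene P, into the part R uniquely
contributes about T and the part redundant with P (Williams-Beer minimum of
specific information).  The per-pair score is the sum over all n-2 partners
of the unique fraction

    PUC(R;T) = sum_P Unq_P(T;R) / I(R;T),        Unq_P = I(T;R) - Rdn(T;R,P)

so a regulator whose information about a target is explained away by many
other genes scores low even when its raw MI is high.  Redundancy is
asymmetric, so for genes appearing on both sides of the analysis the two
directional scores are averaged.  Final edge weights are the average of the
empirical CDFs of the score within its regulator's and its target's score
pools, mapping each score onto (0, 1].

Expression is discretized gene-wise into k equal-width bins with
k = round(sqrt(n_cells)) by default; a binary on/off mode (nonzero count)
is available for very sparse data.  All entropies are in bits; the PUC
ratio itself is independent of the logarithm base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import GeneExpressionMatrix, WeightedEdgeList

__all__ = [
    "DiscretizedMatrix",
    "PIDResult",
    "PUCMatrix",
    "discretize",
    "entropy",
    "mutual_information",
    "specific_information",
    "pid_decompose",
    "puc_scores",
    "normalize_puc",
    "infer_grn",
]

#: negative values larger than this (in absolute value) are real errors;
#: anything smaller is floating-point noise and is clipped to zero.
_CLIP_TOL = 1e-12

#: above this many genes the O(n^3) triplet loop gets slow; warn the caller.
_PANEL_WARN = 2000


@dataclass
class DiscretizedMatrix:
    """Per-gene equal-width bin assignment of an expression matrix."""

    bins: np.ndarray  # (genes, cells) int
    k: int
    edges: list[np.ndarray]  # per-gene bin boundaries (k+1 values)
    gene_ids: list[str]


@dataclass
class PIDResult:
    """Unique / redundant / synergistic split of I(T; R, P)."""

    mi: float  # I(T;R)
    redundancy: float  # Rdn(T; R, P)
    unique_r: float  # Unq(T;R) = I(T;R) - Rdn
    unique_p: float  # Unq(T;P) = I(T;P) - Rdn
    synergy: float  # I(T;(R,P)) - Unq_R - Unq_P - Rdn


@dataclass
class PUCMatrix:
    """Directional (post-symmetrization) PUC scores for regulator x target."""

    puc: np.ndarray  # (len(regulators), len(targets)); NaN for R == T
    regulators: list[str]
    targets: list[str]


def discretize(
    expr: GeneExpressionMatrix,
    k: int | None = None,
    mode: str = "equal_width",
) -> DiscretizedMatrix:
    """Bin each gene's profile into k equal-width bins over its own range.

    Bins are half-open with the last bin closed, so a value exactly on an
    interior boundary falls into the right-hand bin and the per-gene maximum
    into bin k-1.  ``mode="binary"`` instead bins on detection: 1 iff the
    raw count is nonzero.  Default k is the nearest integer to sqrt(m).
    """
    m = expr.n_cells
    if m < 4:
        raise ValueError("need at least 4 cells to discretize")
    if mode == "binary":
        bins = (expr.values > 0).astype(np.int64)
        edges = [np.array([0.0, 0.5, 1.0])] * expr.n_genes
        return DiscretizedMatrix(bins, 2, edges, list(expr.gene_ids))
    if mode != "equal_width":
        raise ValueError(f"unknown mode {mode!r}")
    if k is None:
        k = int(round(np.sqrt(m)))
    if k < 2:
        raise ValueError("k must be >= 2")
    x = expr.lognorm
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.floor((x - lo) / np.where(span > 0, span, 1.0) * k).astype(np.int64)
    idx = np.clip(idx, 0, k - 1)
    idx[np.broadcast_to(span == 0, idx.shape)] = 0  # constant gene -> one bin
    edges = [np.linspace(lo[g, 0], hi[g, 0], k + 1) for g in range(expr.n_genes)]
    return DiscretizedMatrix(idx, k, edges, list(expr.gene_ids))


def entropy(bins: np.ndarray, base: float = 2.0) -> float:
    """Plug-in entropy of a discrete sample, by default in bits."""
    bins = np.asarray(bins)
    if bins.size == 0:
        raise ValueError("empty sample")
    _, counts = np.unique(bins, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    kx = int(x.max()) + 1
    ky = int(y.max()) + 1
    return np.bincount(x * ky + y, minlength=kx * ky).reshape(kx, ky).astype(float)


def mutual_information(x: np.ndarray, y: np.ndarray, base: float = 2.0) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), clipped at zero."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    joint = _joint_counts(x, y)
    return _mi_from_joint(joint, base)


def _entropy_of(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _mi_from_joint(joint: np.ndarray, base: float = 2.0) -> float:
    n = joint.sum()
    p = joint / n
    mi = (
        _entropy_of(p.sum(axis=1), base)
        + _entropy_of(p.sum(axis=0), base)
        - _entropy_of(p.ravel(), base)
    )
    return max(mi, 0.0) if mi > -_CLIP_TOL else _raise_negative(mi)


def _raise_negative(v: float) -> float:  # pragma: no cover - defensive
    raise FloatingPointError(f"information quantity {v} below clip tolerance")


def specific_information(joint: np.ndarray, t: int, base: float = 2.0) -> float:
    """Information the source provides about one target outcome t.

    ``joint`` is a (target-bin x source-bin) count or probability table.
    I_spec(T=t;R) = sum_r p(r|t) log[ p(t|r) / p(t) ], which equals the
    Kullback-Leibler divergence of p(r|t) from p(r) and is therefore
    non-negative.  Its p(t)-weighted average over t recovers I(T;R).
    """
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    pt = joint[t].sum() / total
    if pt <= 0:
        raise ValueError(f"p(t)=0 for target bin {t}")
    p_r_given_t = joint[t] / joint[t].sum()
    p_r = joint.sum(axis=0) / total
    mask = p_r_given_t > 0
    val = (p_r_given_t[mask] * (np.log(p_r_given_t[mask] / p_r[mask]) / np.log(base))).sum()
    return float(max(val, 0.0))


def _specific_information_rows(joint: np.ndarray, base: float = 2.0) -> np.ndarray:
    """Vector of I_spec(T=t; R) for every target bin t (0 where p(t)=0)."""
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    row_sums = joint.sum(axis=1, keepdims=True)
    p_r = joint.sum(axis=0) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        p_r_given_t = np.where(row_sums > 0, joint / np.where(row_sums > 0, row_sums, 1.0), 0.0)
        ratio = np.where(p_r > 0, p_r_given_t / np.where(p_r > 0, p_r, 1.0), 0.0)
        terms = np.where(p_r_given_t > 0, p_r_given_t * np.log(ratio) / np.log(base), 0.0)
    return np.clip(terms.sum(axis=1), 0.0, None)


def pid_decompose(
    t: np.ndarray, r: np.ndarray, p: np.ndarray, base: float = 2.0
) -> PIDResult:
    """Split I(T; R, P) into unique, redundant and synergistic parts.

    Redundancy is the Williams-Beer minimum: for each target outcome the
    smaller of the two sources' specific informations, averaged under p(t).
    Synergy is what the joint source adds beyond both unique parts and the
    redundancy.
    """
    t = np.asarray(t)
    r = np.asarray(r)
    p = np.asarray(p)
    if not (t.shape == r.shape == p.shape):
        raise ValueError("samples must have equal length")
    jr = _joint_counts(t, r)
    jp = _joint_counts(t, p)
    pt_r = jr.sum(axis=1) / jr.sum()
    spec_r = _specific_information_rows(jr, base)
    spec_p = _specific_information_rows(jp, base)
    # jr and jp share the target marginal but may differ in the number of
    # occupied target bins; align on the common length.
    kt = max(len(spec_r), len(spec_p))
    sr = np.zeros(kt)
    sp = np.zeros(kt)
    pt = np.zeros(kt)
    sr[: len(spec_r)] = spec_r
    sp[: len(spec_p)] = spec_p
    pt[: len(pt_r)] = pt_r
    rdn = float((pt * np.minimum(sr, sp)).sum())
    mi_r = _mi_from_joint(jr, base)
    mi_p = _mi_from_joint(jp, base)
    unq_r = max(mi_r - rdn, 0.0)
    unq_p = max(mi_p - rdn, 0.0)
    # joint source: pair (R, P) encoded as one variable
    rp = r * (int(p.max()) + 1) + p
    mi_joint = _mi_from_joint(_joint_counts(t, rp), base)
    syn = mi_joint - unq_r - unq_p - rdn
    return PIDResult(mi=mi_r, redundancy=rdn, unique_r=unq_r, unique_p=unq_p, synergy=syn)


def _pair_tables(bins: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs MI, specific-information tensor and target marginals.

    Returns ``(mi, spec, pt)`` where ``mi[a, b] = I(a;b)`` in bits,
    ``spec[tgt, src, t] = I_spec(T=t; src)`` and ``pt[g, t]`` is gene g's
    bin marginal.  spec is O(n^2 k) memory — panels are expected to be at
    most a couple thousand genes.
    """
    n, m = bins.shape
    mi = np.zeros((n, n))
    spec = np.zeros((n, n, k))
    pt = np.zeros((n, k))
    for g in range(n):
        pt[g] = np.bincount(bins[g], minlength=k) / m
    log_base = np.log(2.0)
    for a in range(n):
        ba = bins[a]
        for b in range(a + 1, n):
            joint = np.bincount(ba * k + bins[b], minlength=k * k).reshape(k, k).astype(float)
            p = joint / m
            h_a = _entropy_of(p.sum(axis=1), 2.0)
            h_b = _entropy_of(p.sum(axis=0), 2.0)
            h_ab = _entropy_of(p.ravel(), 2.0)
            mival = h_a + h_b - h_ab
            if mival < _CLIP_TOL:  # exact independence up to float noise
                mival = 0.0
            mi[a, b] = mi[b, a] = mival
            spec[a, b] = _spec_rows_padded(joint, k)
            spec[b, a] = _spec_rows_padded(joint.T, k)
    return mi, spec, pt


def _spec_rows_padded(joint: np.ndarray, k: int) -> np.ndarray:
    rows = _specific_information_rows(joint)
    out = np.zeros(k)
    out[: len(rows)] = rows
    return out


def puc_scores(
    disc: DiscretizedMatrix,
    regulators: list[str],
    targets: list[str] | None = None,
) -> PUCMatrix:
    """Directional PUC for every regulator-target pair over the gene panel.

    The partner set for a pair is every other gene in the panel (n - 2
    partners).  When a regulator also appears in the target set the stored
    score is the mean of the two directional scores; pairs with zero MI
    score zero.
    """
    if targets is None:
        targets = list(disc.gene_ids)
    gene_pos = {g: i for i, g in enumerate(disc.gene_ids)}
    missing = [g for g in set(regulators) | set(targets) if g not in gene_pos]
    if missing:
        raise KeyError(f"genes not in discretized panel: {missing[:5]}")
    n = len(disc.gene_ids)
    if n < 3:
        raise ValueError("PUC needs at least 3 genes (n - 2 partners)")
    if not regulators:
        raise ValueError("empty regulator list")
    mi, spec, pt = _pair_tables(disc.bins, disc.k)
    target_set = set(targets)

    def directional(ri: int, ti: int) -> float:
        """PUC(R;T) summed over all partners except R and T."""
        i_rt = mi[ri, ti]
        if i_rt <= 0:
            return 0.0
        # Rdn(T; R, P) for all P at once, then Unq_P = I - Rdn
        mins = np.minimum(spec[ti, ri][None, :], spec[ti])  # (n, k)
        rdn = mins @ pt[ti]  # (n,)
        unq = np.clip(i_rt - rdn, 0.0, None)
        unq[ri] = 0.0
        unq[ti] = 0.0
        return float(unq.sum() / i_rt)

    cache: dict[tuple[int, int], float] = {}

    def cached(ri: int, ti: int) -> float:
        key = (ri, ti)
        if key not in cache:
            cache[key] = directional(ri, ti)
        return cache[key]

    out = np.full((len(regulators), len(targets)), np.nan)
    for i, reg in enumerate(regulators):
        ri = gene_pos[reg]
        for j, tgt in enumerate(targets):
            ti = gene_pos[tgt]
            if ri == ti:
                continue
            score = cached(ri, ti)
            if reg in target_set:  # both directions defined: average them
                score = 0.5 * (score + cached(ti, ri))
            out[i, j] = score
    return PUCMatrix(out, list(regulators), list(targets))


def normalize_puc(puc: PUCMatrix) -> WeightedEdgeList:
    """Map PUC scores onto (0, 1] via per-gene empirical CDFs.

    For each edge the weight is the mean of F_R and F_T, where F_X is the
    fraction of all scores involving gene X (as either endpoint) that are
    less than or equal to the edge's score.  The gene-wise pooling makes
    hub regulators and promiscuous targets comparable on one scale.
    """
    pools: dict[str, list[float]] = {}
    for i, reg in enumerate(puc.regulators):
        for j, tgt in enumerate(puc.targets):
            v = puc.puc[i, j]
            if np.isnan(v):
                continue
            pools.setdefault(reg, []).append(v)
            if tgt != reg:
                pools.setdefault(tgt, []).append(v)
    arrays = {g: np.sort(np.asarray(vals)) for g, vals in pools.items()}

    def ecdf(g: str, v: float) -> float:
        a = arrays[g]
        return float(np.searchsorted(a, v, side="right") / len(a))

    edges = []
    for i, reg in enumerate(puc.regulators):
        for j, tgt in enumerate(puc.targets):
            v = puc.puc[i, j]
            if np.isnan(v):
                continue
            edges.append((reg, tgt, 0.5 * (ecdf(reg, v) + ecdf(tgt, v))))
    return WeightedEdgeList(edges)


def infer_grn(
    expr: GeneExpressionMatrix,
    regulators: list[str],
    targets: list[str] | None = None,
    k: int | None = None,
    mode: str = "equal_width",
) -> WeightedEdgeList:
    """Full inference: discretize, score all pairs, ECDF-normalize.

    ``regulators`` are typically the measured TFs; ``targets`` defaults to
    every gene in the (already filtered) matrix.  Deterministic for a fixed
    input.
    """
    if not regulators:
        raise ValueError("empty regulator list")
    if expr.n_genes > _PANEL_WARN:
        warnings.warn(
            f"{expr.n_genes} genes: the triplet decomposition is cubic in panel "
            "size; consider restricting to a variable-gene panel",
            stacklevel=2,
        )
    disc = discretize(expr, k=k, mode=mode)
    scores = puc_scores(disc, regulators, targets)
    return normalize_puc(scores)
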