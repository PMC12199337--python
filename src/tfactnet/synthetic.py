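"""Synthetic single-cell data with a known TF-target ground truth.

The generator emulates the structure the framework assumes: a handful of
TFs each drive a block of target genes through a latent per-cell activity;
cells come in blocks (cell types, or perturbation arms with one control
arm); counts are negative-binomial with Bernoulli dropout on top; prior
evidence is the true network corrupted with false negatives and false
positives.  Every function is deterministic for a fixed seed.

Two presets mirror the two study designs the framework targets:

* ``crispr`` — one control arm plus one knockout arm per TF.  All TFs are
  active (latent = base + delta) everywhere except in their own knockout
  arm (base - delta), so the targeted TF's own transcript and its targets
  both drop — which is what the arm QC and the AUROC benchmark assume.
* ``celltypes`` — each TF is active only in its own cell type; no
  perturbation.  Used for cell-type-specificity recovery.

Besides the network genes, the measured panel includes background genes
regulated by no TF (heterogeneous baselines, no latent signal).  Real
matrices are dominated by genes outside any studied regulon; the
background keeps gene-gene null behavior and the per-TF weight
distribution of the integrated network realistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    CellAnnotation,
    GeneExpressionMatrix,
    PerturbationDesign,
    WeightedEdgeList,
)

__all__ = ["SyntheticTruth", "generate_truth", "simulate_counts", "corrupt_prior"]


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset."""

    true_edges: WeightedEdgeList
    tf_activity_latent: np.ndarray  # (n_tfs, n_cells)
    tf_ids: list[str]
    gene_ids: list[str]  # tfs + targets + background, in order
    cell_types: CellAnnotation
    design: PerturbationDesign
    seed: int

    def targets_of(self, tf: str) -> list[str]:
        return [t for r, t, _ in self.true_edges.edges if r == tf]


def generate_truth(
    n_tfs: int = 5,
    targets_per_tf: int = 30,
    n_types: int | None = None,
    cells_per_type: int = 200,
    seed: int = 0,
    preset: str = "crispr",
    base: float = 0.0,
    delta: float = 2.0,
    overlap_frac: float = 0.0,
    n_background: int = 150,
    weight_range: tuple[float, float] = (0.5, 1.0),
) -> SyntheticTruth:
    """Draw a ground-truth network, latent activities and a cell design.

    Target sets are disjoint by default; ``overlap_frac`` reassigns that
    fraction of each TF's targets to genes shared with the previous TF.
    Latent activity is ``base`` plus ``delta`` where the TF is active and
    ``base - delta`` in its knockout arm.
    """
    if min(n_tfs, targets_per_tf, cells_per_type) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i:02d}" for i in range(n_tfs)]
    target_ids = [f"G{i:04d}" for i in range(n_tfs * targets_per_tf)]
    background_ids = [f"B{i:04d}" for i in range(n_background)]
    edges: list[tuple[str, str, float]] = []
    for f, tf in enumerate(tf_ids):
        own = target_ids[f * targets_per_tf : (f + 1) * targets_per_tf]
        if overlap_frac > 0 and f > 0:
            n_shared = int(round(overlap_frac * targets_per_tf))
            prev = target_ids[(f - 1) * targets_per_tf : f * targets_per_tf]
            own = prev[:n_shared] + own[n_shared:]
        for t in own:
            w = rng.uniform(*weight_range)
            edges.append((tf, t, float(w)))

    if preset == "crispr":
        arms = {"control": (None, "control")}
        arm_labels: list[str] = ["control"] * cells_per_type
        for tf in tf_ids:
            arms[f"ko_{tf}"] = (tf, "knockout")
            arm_labels += [f"ko_{tf}"] * cells_per_type
        m = len(arm_labels)
        cell_ids = [f"C{i:05d}" for i in range(m)]
        arm_of = dict(zip(cell_ids, arm_labels))
        design = PerturbationDesign(arm_of, arms)
        labels = CellAnnotation(dict(zip(cell_ids, arm_labels)))
        latent = np.full((n_tfs, m), base + delta)
        for f, tf in enumerate(tf_ids):
            ko = np.array([a == f"ko_{tf}" for a in arm_labels])
            latent[f, ko] = base - delta
    elif preset == "celltypes":
        if n_types is None:
            n_types = n_tfs
        type_labels: list[str] = []
        for t in range(n_types):
            type_labels += [f"type{t}"] * cells_per_type
        m = len(type_labels)
        cell_ids = [f"C{i:05d}" for i in range(m)]
        labels = CellAnnotation(dict(zip(cell_ids, type_labels)))
        design = PerturbationDesign(
            {c: "control" for c in cell_ids}, {"control": (None, "control")}
        )
        latent = np.full((n_tfs, m), base)
        for f in range(n_tfs):
            active = np.array([lab == f"type{f % n_types}" for lab in type_labels])
            latent[f, active] = base + delta
    else:
        raise ValueError(f"unknown preset {preset!r}")

    return SyntheticTruth(
        true_edges=WeightedEdgeList(edges),
        tf_activity_latent=latent,
        tf_ids=tf_ids,
        gene_ids=tf_ids + target_ids + background_ids,
        cell_types=labels,
        design=design,
        seed=seed,
    )


def simulate_counts(
    truth: SyntheticTruth,
    mean_depth: float = 5000.0,
    noise_disp: float = 0.3,
    dropout_rate: float = 0.1,
    seed: int | None = None,
) -> GeneExpressionMatrix:
    """Negative-binomial counts with Bernoulli dropout from the latent truth.

    A target gene's log-mean is its baseline plus (edge weight x latent TF
    activity); a TF's own transcript follows its latent activity directly;
    background genes keep their baseline.  Means are scaled so the average
    library size is ``mean_depth``, counts are NB with dispersion
    ``noise_disp`` (variance mu + disp mu^2) and each entry is then zeroed
    with probability ``dropout_rate``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    genes = truth.gene_ids
    n, m = len(genes), truth.tf_activity_latent.shape[1]
    gene_pos = {g: i for i, g in enumerate(genes)}
    baseline = rng.uniform(-1.0, 1.0, size=n)
    logmu = np.tile(baseline[:, None], (1, m))
    for f, tf in enumerate(truth.tf_ids):
        logmu[gene_pos[tf]] += truth.tf_activity_latent[f]
    for r, t, w in truth.true_edges.edges:
        f = truth.tf_ids.index(r)
        logmu[gene_pos[t]] += w * truth.tf_activity_latent[f]
    mu = np.exp(logmu)
    mu *= mean_depth / mu.sum(axis=0).mean()
    if noise_disp > 0:
        shape = 1.0 / noise_disp
        counts = rng.negative_binomial(shape, shape / (shape + mu)).astype(float)
    else:
        counts = rng.poisson(mu).astype(float)
    if dropout_rate > 0:
        counts *= rng.random(counts.shape) >= dropout_rate
    cell_ids = list(truth.cell_types.labels)
    return GeneExpressionMatrix(counts, list(genes), cell_ids)


def corrupt_prior(
    true_edges: WeightedEdgeList,
    fpr: float = 0.2,
    fnr: float = 0.2,
    n_sources: int = 3,
    seed: int = 0,
    gene_pool: list[str] | None = None,
    noise_scale: float = 0.5,
) -> dict[str, WeightedEdgeList]:
    """Independent noisy views of the true network, min-max scaled.

    Each source drops true edges with probability ``fnr`` and adds enough
    random false edges (regulator from the true TFs, target from
    ``gene_pool``) that false edges make up about ``fpr`` of the source.
    Weights are the true weight (0 for false edges) plus uniform noise on
    [0, noise_scale], min-max scaled within the source.
    """
    if not (0.0 <= fpr < 1.0 and 0.0 <= fnr < 1.0):
        raise ValueError("fpr and fnr must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    tfs = sorted({r for r, _, _ in true_edges.edges})
    true_pairs = {(r, t) for r, t, _ in true_edges.edges}
    if gene_pool is None:
        gene_pool = sorted({t for _, t, _ in true_edges.edges})
    sources: dict[str, WeightedEdgeList] = {}
    for s in range(n_sources):
        kept = [e for e in true_edges.edges if rng.random() >= fnr]
        n_false = int(round(len(kept) * fpr / (1.0 - fpr))) if fpr > 0 else 0
        false_pairs: set[tuple[str, str]] = set()
        guard = 0
        while len(false_pairs) < n_false and guard < 100 * n_false + 100:
            guard += 1
            pair = (tfs[rng.integers(len(tfs))], gene_pool[rng.integers(len(gene_pool))])
            if pair not in true_pairs and pair[0] != pair[1]:
                false_pairs.add(pair)
        raw = [(r, t, w + rng.uniform(0, noise_scale)) for r, t, w in kept]
        raw += [(r, t, rng.uniform(0, noise_scale)) for r, t in sorted(false_pairs)]
        w = np.array([e[2] for e in raw])
        lo, hi = w.min(), w.max()
        scaled = (w - lo) / (hi - lo) if hi > lo else np.ones_like(w)
        sources[f"source{s}"] = WeightedEdgeList(
            [(r, t, float(wi)) for (r, t, _), wi in zip(raw, scaled)]
        )
    return sources
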