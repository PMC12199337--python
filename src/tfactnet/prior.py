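"""Per-source edge weights for prior TF-target evidence.

Four evidence classes are supported, each supplied as a user table:
manually curated interactions (publication count, assay class, interaction
type), ChIP-seq binding sites (distance-decay around the TSS), motif scans
(conservation-weighted match significance) and TF knockout differential
expression.  Each source yields a weighted edge list; ``assemble_prior``
min-max scales every source onto [0, 1] so the logistic integration step
can treat them uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import WeightedEdgeList

__all__ = [
    "CuratedEvidence",
    "ChipEvidence",
    "MotifEvidence",
    "KnockoutEvidence",
    "curated_weight",
    "chip_weight",
    "median_distance",
    "motif_weight",
    "knockout_edges",
    "assemble_prior",
    "chip_distances",
    "map_orthologs",
    "DEFAULT_METHOD_SCORES",
    "DEFAULT_TYPE_SCORES",
]

METHOD_CLASSES = ("small_mid", "high_throughput", "unknown")
INTERACTION_TYPES = ("physical", "direct", "interaction", "activation", "inhibition", "unknown")

#: targeted low-throughput assays (EMSA, footprinting, Y1H ...) are trusted
#: most; ChIP-chip/seq style surveys less; unprovenanced entries least.
DEFAULT_METHOD_SCORES = {"small_mid": 1.0, "high_throughput": 0.6, "unknown": 0.3}
DEFAULT_TYPE_SCORES = {
    "physical": 1.0,
    "direct": 1.0,
    "activation": 0.7,
    "inhibition": 0.7,
    "interaction": 0.7,
    "unknown": 0.3,
}


@dataclass
class CuratedEvidence:
    regulator: str
    target: str
    n_publications: int = 1
    method_class: str = "unknown"
    interaction_type: str = "unknown"

    def __post_init__(self) -> None:
        if self.n_publications < 1:
            raise ValueError("n_publications must be >= 1")
        if self.method_class not in METHOD_CLASSES:
            raise ValueError(f"unknown method class {self.method_class!r}")
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")


@dataclass
class ChipEvidence:
    regulator: str
    target_gene: str
    distances: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.distances):
            raise ValueError("site-TSS distances must be non-negative")


@dataclass
class MotifEvidence:
    regulator: str
    target: str
    fimo_p: float
    phastcons: float
    phylop: float

    def __post_init__(self) -> None:
        if not (0.0 < self.fimo_p <= 1e-4):
            raise ValueError("motif matches must be pre-filtered to FIMO p <= 1e-4")
        if not (0.0 <= self.phastcons <= 1.0):
            raise ValueError("phastcons must lie in [0, 1]")


@dataclass
class KnockoutEvidence:
    dataset: str
    tf: str
    tf_p: float
    tf_logfc: float
    target: str
    target_p: float
    target_logfc: float

    def __post_init__(self) -> None:
        for p in (self.tf_p, self.target_p):
            if not (0.0 < p <= 1.0):
                raise ValueError("p-values must lie in (0, 1]")


def saturating_publication_score(n: int, cap: int = 5) -> float:
    """Credit up to ``cap`` independent publications, linearly."""
    return min(n, cap) / cap


def curated_weight(
    ev: CuratedEvidence,
    coeffs: dict[str, float] | None = None,
    method_scores: dict[str, float] | None = None,
    type_scores: dict[str, float] | None = None,
    publication_score=saturating_publication_score,
) -> float:
    """Convex combination of publication, assay and interaction-type credit.

    weight = (K_p S_p + K_m S_m + K_t S_t) / (K_p + K_m + K_t), with the
    three dimension scores in [0, 1] so the result is too.
    """
    coeffs = coeffs or {"K_p": 1.0, "K_m": 1.0, "K_t": 1.0}
    if any(v <= 0 for v in coeffs.values()):
        raise ValueError("coefficients must be positive")
    method_scores = method_scores or DEFAULT_METHOD_SCORES
    type_scores = type_scores or DEFAULT_TYPE_SCORES
    s_p = publication_score(ev.n_publications)
    s_m = method_scores[ev.method_class]
    s_t = type_scores[ev.interaction_type]
    k_p, k_m, k_t = coeffs["K_p"], coeffs["K_m"], coeffs["K_t"]
    return (k_p * s_p + k_m * s_m + k_t * s_t) / (k_p + k_m + k_t)


def median_distance(all_distances: list[int] | np.ndarray) -> float:
    """Median site-TSS distance for one TF; the decay scale in chip_weight."""
    arr = np.asarray(all_distances, dtype=float)
    if arr.size == 0:
        raise ValueError("no distances to take a median of")
    return float(np.median(arr))


def chip_weight(ev: ChipEvidence, d_tf: float, k: float = 1.0) -> float:
    """Sum of exponential distance decays over the TF's sites near a gene.

    Each binding site contributes exp(-d_i / (k * D_TF)) where D_TF is the
    TF's median site-TSS distance; multiple sites add up, so genes with
    several proximal sites outweigh single distal ones.
    """
    if d_tf <= 0:
        raise ValueError("d_tf must be positive")
    if not ev.distances:
        return 0.0
    d = np.asarray(ev.distances, dtype=float)
    return float(np.exp(-d / (k * d_tf)).sum())


def motif_weight(ev: MotifEvidence) -> float:
    """sqrt(phastcons * max(phylop, 0) * -log10 p); 0 for non-conserved sites."""
    return float(
        np.sqrt(ev.phastcons * max(ev.phylop, 0.0) * (-np.log10(ev.fimo_p)))
    )


def knockout_edges(evs: list[KnockoutEvidence]) -> WeightedEdgeList:
    """Edges from knockout DE: weight -log10(p) of the target's change.

    Only datasets in which the knocked-out TF itself is significantly down
    (p < 0.05, logFC < -1) are trusted; within them, targets must be
    differentially expressed (p < 0.05, |logFC| > 1).  Duplicate TF-target
    pairs across datasets keep the strongest (smallest-p) evidence.
    """
    kept_datasets = {
        ev.dataset for ev in evs if ev.tf_p < 0.05 and ev.tf_logfc < -1.0
    }
    best: dict[tuple[str, str], float] = {}
    for ev in evs:
        if ev.dataset not in kept_datasets:
            continue
        if ev.target_p < 0.05 and abs(ev.target_logfc) > 1.0:
            w = -np.log10(ev.target_p)
            key = (ev.tf, ev.target)
            if w > best.get(key, -np.inf):
                best[key] = w
    return WeightedEdgeList([(r, t, w) for (r, t), w in best.items()])


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def assemble_prior(sources: dict[str, WeightedEdgeList]) -> dict[str, WeightedEdgeList]:
    """Min-max scale every source's weights onto [0, 1].

    Empty sources are dropped with a warning; a constant-weight source maps
    to all ones (presence is its only signal).
    """
    if not sources:
        raise ValueError("no prior sources supplied")
    out: dict[str, WeightedEdgeList] = {}
    for name, net in sources.items():
        if len(net) == 0:
            warnings.warn(f"prior source {name!r} is empty; dropped", stacklevel=2)
            continue
        w = _minmax(np.array([e[2] for e in net.edges], dtype=float))
        out[name] = WeightedEdgeList(
            [(r, t, float(wi)) for (r, t, _), wi in zip(net.edges, w)]
        )
    return out


def chip_distances(
    sites: pd.DataFrame, tss: pd.DataFrame
) -> dict[tuple[str, str], list[int]]:
    """Site-TSS distances from a BED-like site table and a TSS table.

    ``sites`` needs columns (chrom, start, end, tf) with 0-based half-open
    coordinates; ``tss`` needs (gene, chrom, tss).  Each site is assigned to
    the nearest TSS on its chromosome (distance from the site midpoint,
    strand ignored); returns {(tf, gene): [distances...]}.
    """
    out: dict[tuple[str, str], list[int]] = {}
    by_chrom = {
        chrom: grp.sort_values("tss").reset_index(drop=True)
        for chrom, grp in tss.groupby("chrom")
    }
    for _, row in sites.iterrows():
        grp = by_chrom.get(row["chrom"])
        if grp is None:
            continue
        mid = (int(row["start"]) + int(row["end"])) // 2
        pos = grp["tss"].to_numpy()
        i = int(np.argmin(np.abs(pos - mid)))
        gene = str(grp.loc[i, "gene"])
        out.setdefault((str(row["tf"]), gene), []).append(int(abs(pos[i] - mid)))
    return out


def map_orthologs(net: WeightedEdgeList, ortholog_table: pd.DataFrame) -> WeightedEdgeList:
    """Translate a network through a two-column (source gene, mapped gene)
    table; one-to-many mappings expand into multiple edges, keeping the
    maximum weight on collisions."""
    mapping: dict[str, list[str]] = {}
    src_col, dst_col = ortholog_table.columns[:2]
    for a, b in zip(ortholog_table[src_col].astype(str), ortholog_table[dst_col].astype(str)):
        mapping.setdefault(a, []).append(b)
    best: dict[tuple[str, str], float] = {}
    for r, t, w in net.edges:
        for r2 in mapping.get(r, []):
            for t2 in mapping.get(t, []):
                key = (r2, t2)
                if w > best.get(key, -np.inf):
                    best[key] = w
    return WeightedEdgeList([(r, t, w) for (r, t), w in best.items()])
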