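"""Core in-memory containers shared by every pipeline stage.

The containers are deliberately thin: a counts matrix with a log-normalized
layer, a cell-type annotation, weighted directed edge lists (inferred GRNs,
prior evidence networks and integrated networks all share one shape), regulon
sets and TF-by-cell activity matrices.  Gene and cell identifiers are opaque
strings; no symbol mapping happens anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneExpressionMatrix",
    "CellAnnotation",
    "WeightedEdgeList",
    "RegulonSet",
    "ActivityMatrix",
    "PerturbationDesign",
]

#: library-size target used when log-normalizing counts (counts per 10k).
DEFAULT_LOGNORM_TARGET = 1e4


def lognormalize(counts: np.ndarray, target: float = DEFAULT_LOGNORM_TARGET) -> np.ndarray:
    """log2(1 + count * target / cell_total) per cell (column).

    Cells with zero total counts are left at zero rather than dividing by
    zero; such cells carry no information for any downstream rank statistic.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log2(1.0 + counts * (target / safe))


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")
    return ids


@dataclass
class GeneExpressionMatrix:
    """Genes x cells raw counts plus a log-normalized layer.

    ``values`` holds non-negative raw counts; ``lognorm`` is
    ``log2(1 + count * target / cell_total)`` and is computed on
    construction unless supplied explicitly.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    lognorm: np.ndarray | None = None
    lognorm_target: float = DEFAULT_LOGNORM_TARGET

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("counts must be finite")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        if self.lognorm is None:
            self.lognorm = lognormalize(self.values, self.lognorm_target)
        else:
            self.lognorm = np.asarray(self.lognorm, dtype=float)
            if self.lognorm.shape != self.values.shape:
                raise ValueError("lognorm layer shape differs from counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"gene {e.args[0]!r} not in matrix") from None

    def subset_genes(self, genes: Sequence[str]) -> "GeneExpressionMatrix":
        idx = self.gene_index(genes)
        return GeneExpressionMatrix(
            self.values[idx], [self.gene_ids[i] for i in idx], list(self.cell_ids),
            lognorm=self.lognorm[idx], lognorm_target=self.lognorm_target,
        )

    def subset_cells(self, cells: Sequence[str]) -> "GeneExpressionMatrix":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in cells], dtype=int)
        return GeneExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.cell_ids[i] for i in idx],
            lognorm=self.lognorm[:, idx], lognorm_target=self.lognorm_target,
        )

    def to_frame(self, layer: str = "values") -> pd.DataFrame:
        data = self.values if layer == "values" else self.lognorm
        return pd.DataFrame(data, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CellAnnotation:
    """Cell id -> cell-type label; every cell has exactly one label."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}
        if not self.labels:
            raise ValueError("annotation is empty")

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def for_cells(self, cell_ids: Sequence[str]) -> np.ndarray:
        missing = [c for c in cell_ids if c not in self.labels]
        if missing:
            raise KeyError(f"cells without annotation: {missing[:5]}")
        return np.array([self.labels[c] for c in cell_ids])


@dataclass
class WeightedEdgeList:
    """Directed (regulator, target, weight) triples with unique pairs."""

    edges: list[tuple[str, str, float]]
    directed: bool = True

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        clean: list[tuple[str, str, float]] = []
        for r, t, w in self.edges:
            w = float(w)
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight on edge ({r}, {t})")
            key = (str(r), str(t))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            clean.append((key[0], key[1], w))
        self.edges = clean

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    @property
    def regulators(self) -> list[str]:
        return sorted({r for r, _, _ in self.edges})

    def targets_of(self, regulator: str) -> list[tuple[str, float]]:
        return [(t, w) for r, t, w in self.edges if r == regulator]

    def weight_map(self) -> dict[tuple[str, str], float]:
        return {(r, t): w for r, t, w in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["regulator", "target", "weight"])


@dataclass
class RegulonSet:
    """TF -> positively regulated targets with likelihood weights in (0, 1]."""

    regulons: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            names = [t for t, _ in targets]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate targets in regulon {tf}")
            for t, lik in targets:
                if not (0.0 < lik <= 1.0):
                    raise ValueError(
                        f"likelihood {lik} for ({tf}, {t}) outside (0, 1]"
                    )

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self):
        return iter(self.regulons.items())

    def targets(self, tf: str) -> list[str]:
        return [t for t, _ in self.regulons[tf]]

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.regulons)


@dataclass
class ActivityMatrix:
    """TF x cell enrichment scores.  NaN marks activities that could not be
    computed (regulon with no expressed member in any cell)."""

    scores: np.ndarray
    tf_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.tf_ids = _check_unique(self.tf_ids, "tf")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if self.scores.shape != (len(self.tf_ids), len(self.cell_ids)):
            raise ValueError("score matrix shape does not match ids")

    def row(self, tf: str) -> np.ndarray:
        return self.scores[self.tf_ids.index(tf)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.tf_ids, columns=self.cell_ids)


@dataclass
class PerturbationDesign:
    """Assignment of cells to perturbation arms.

    ``arm_of`` maps cell id -> arm label; ``arms`` maps arm label ->
    (targeted TF or None for the control arm, direction).  Exactly one
    control arm is required.
    """

    arm_of: dict[str, str]
    arms: dict[str, tuple[str | None, str]]  # arm -> (tf, "knockout"|"overexpression"|"control")

    def __post_init__(self) -> None:
        controls = [a for a, (tf, d) in self.arms.items() if tf is None]
        if len(controls) != 1:
            raise ValueError("design needs exactly one control arm")
        for arm in set(self.arm_of.values()):
            if arm not in self.arms:
                raise ValueError(f"cells assigned to undeclared arm {arm!r}")
        for arm, (tf, direction) in self.arms.items():
            if tf is not None and direction not in ("knockout", "overexpression"):
                raise ValueError(f"arm {arm!r}: bad direction {direction!r}")

    @property
    def control_arm(self) -> str:
        return next(a for a, (tf, _) in self.arms.items() if tf is None)

    def cells_in(self, arm: str) -> list[str]:
        return [c for c, a in self.arm_of.items() if a == arm]

    def perturbed_arms(self) -> list[str]:
        return [a for a, (tf, _) in self.arms.items() if tf is not None]
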