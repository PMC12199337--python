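"""Readers and writers for the plain-text formats the pipeline touches.

Expression comes in as a MatrixMarket coordinate triplet directory
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, 10x-style) or a dense
TSV with genes in rows.  Networks travel as three-column TSV edge lists,
regulons as GMT plus a likelihood TSV, annotations and perturbation designs
as small TSVs.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datamodel import (
    ActivityMatrix,
    CellAnnotation,
    GeneExpressionMatrix,
    PerturbationDesign,
    RegulonSet,
    WeightedEdgeList,
)

__all__ = [
    "read_expression",
    "write_expression_mtx",
    "write_expression_tsv",
    "read_annotation",
    "write_annotation",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "write_regulons",
    "read_activity",
    "write_activity",
    "read_design",
    "write_design",
]


def _read_names(path: Path) -> list[str]:
    # genes.tsv may have extra columns (id, symbol); the first is the id
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_expression(
    path: str | os.PathLike,
    lognorm_target: float = 1e4,
) -> GeneExpressionMatrix:
    """Load a counts matrix from an MTX triplet directory or a dense TSV.

    A directory is expected to contain ``matrix.mtx`` (MatrixMarket
    coordinate, 1-based, genes x cells), ``genes.tsv`` and ``barcodes.tsv``.
    A file is parsed as a dense TSV with gene ids in the first column and a
    header row of cell ids.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"no matrix.mtx under {path}")
        mat = spio.mmread(mtx)
        counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        genes = _read_names(path / "genes.tsv")
        cells = _read_names(path / "barcodes.tsv")
        if counts.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix is {counts.shape} but sidecars name "
                f"{len(genes)} genes and {len(cells)} cells"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    if np.any(counts < 0):
        raise ValueError("negative entries in count matrix")
    return GeneExpressionMatrix(counts, genes, cells, lognorm_target=lognorm_target)


def write_expression_mtx(expr: GeneExpressionMatrix, outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(expr.values))
    pd.Series(expr.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(expr.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


def write_expression_tsv(expr: GeneExpressionMatrix, path: str | os.PathLike) -> None:
    expr.to_frame().to_csv(path, sep="\t")


def read_annotation(path: str | os.PathLike) -> CellAnnotation:
    """Two-column TSV: cell id, cell type (header optional but recommended)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation TSV needs two columns: cell_id, cell_type")
    return CellAnnotation(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_annotation(ann: CellAnnotation, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"cell_id": list(ann.labels), "cell_type": list(ann.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | os.PathLike, directed: bool = True) -> WeightedEdgeList:
    df = pd.read_csv(path, sep="\t")
    needed = {"regulator", "target", "weight"}
    if not needed.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(needed)}")
    edges = list(
        zip(df["regulator"].astype(str), df["target"].astype(str), df["weight"].astype(float))
    )
    return WeightedEdgeList(edges, directed=directed)


def write_edge_list(net: WeightedEdgeList, path: str | os.PathLike) -> None:
    net.to_frame().to_csv(path, sep="\t", index=False)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | os.PathLike,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_regulons(regulons: RegulonSet, outdir: str | os.PathLike) -> None:
    """GMT with the TF as set name, plus a TSV carrying likelihood weights."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gmt({tf: [t for t, _ in targets] for tf, targets in regulons},
              outdir / "regulons.gmt")
    rows = [(tf, t, lik) for tf, targets in regulons for t, lik in targets]
    pd.DataFrame(rows, columns=["tf", "target", "likelihood"]).to_csv(
        outdir / "regulons.tsv", sep="\t", index=False
    )


def read_regulons(outdir: str | os.PathLike) -> RegulonSet:
    df = pd.read_csv(Path(outdir) / "regulons.tsv", sep="\t")
    regs: dict[str, list[tuple[str, float]]] = {}
    for tf, target, lik in zip(df["tf"].astype(str), df["target"].astype(str),
                               df["likelihood"].astype(float)):
        regs.setdefault(tf, []).append((target, lik))
    return RegulonSet(regs)


def read_activity(path: str | os.PathLike) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityMatrix(df.to_numpy(dtype=float),
                          [str(i) for i in df.index], [str(c) for c in df.columns])


def write_activity(act: ActivityMatrix, path: str | os.PathLike) -> None:
    act.to_frame().to_csv(path, sep="\t")


def read_design(path: str | os.PathLike) -> PerturbationDesign:
    """TSV with columns cell_id, arm, target_tf, direction.

    The control arm has an empty target_tf (or the literal ``control``
    direction); all other arms name the perturbed TF.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"cell_id", "arm", "target_tf", "direction"}
    if not needed.issubset(df.columns):
        raise ValueError(f"design TSV must have columns {sorted(needed)}")
    arm_of = dict(zip(df["cell_id"], df["arm"]))
    arms: dict[str, tuple[str | None, str]] = {}
    for _, row in df.drop_duplicates("arm").iterrows():
        tf = row["target_tf"] or None
        direction = row["direction"] or ("control" if tf is None else "knockout")
        arms[row["arm"]] = (tf, direction if tf is not None else "control")
    return PerturbationDesign(arm_of, arms)


def write_design(design: PerturbationDesign, path: str | os.PathLike) -> None:
    rows = []
    for cell, arm in design.arm_of.items():
        tf, direction = design.arms[arm]
        rows.append((cell, arm, tf or "", direction))
    pd.DataFrame(rows, columns=["cell_id", "arm", "target_tf", "direction"]).to_csv(
        path, sep="\t", index=False
    )
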