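"""Tab-separated readers and writers for matrices, edge lists and SIF files.

Matrices are genes-in-rows TSV with a header of sample ids and a first
column of gene/marker ids; floats round-trip at full precision (repr).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset, GRNModel
from .inference import InferenceResult, LRBIResults

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_dataset",
    "write_dataset",
    "write_network",
    "read_network_matrix",
    "read_truth",
    "write_truth",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-in-rows TSV matrix; validates numeric body and unique ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    return df


def write_matrix(matrix: np.ndarray, path: str | Path, gene_ids, sample_ids=None) -> None:
    matrix = np.asarray(matrix)
    if sample_ids is None:
        sample_ids = [f"s{k + 1}" for k in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, index=list(gene_ids), columns=list(sample_ids))
    df.index.name = "id"
    # repr-precision floats so read/write round-trips bit-exactly
    df.to_csv(path, sep="\t", float_format=None)


def read_dataset(expr_path: str | Path, geno_path: str | Path) -> Dataset:
    """Load aligned expression and genotype TSVs into a :class:`Dataset`.

    Sample columns are aligned on the header intersection in expression-file
    order; rows are aligned by gene id. Every expression gene must have a
    marker row.
    """
    expr = read_matrix(expr_path)
    geno = read_matrix(geno_path)
    common = [c for c in expr.columns if c in set(geno.columns)]
    if not common:
        raise ValueError(
            f"no shared sample ids between {expr_path} and {geno_path}"
        )
    missing = [g for g in expr.index if g not in set(geno.index)]
    if missing:
        raise ValueError(f"{geno_path}: missing marker rows for genes {missing}")
    geno = geno.loc[expr.index, common]
    X = geno.to_numpy()
    X_int = X.astype(int)
    if not np.array_equal(X, X_int):
        raise ValueError(f"{geno_path}: genotype entries must be integer codes")
    codes = tuple(sorted(set(np.unique(X_int).tolist()) | {0, 1, 2}))
    return Dataset(
        Y=expr[common].to_numpy(dtype=float),
        X=X_int,
        gene_ids=tuple(str(g) for g in expr.index),
        genotype_codes=codes,
    )


def write_dataset(dataset: Dataset, expr_path: str | Path, geno_path: str | Path) -> None:
    sample_ids = [f"s{k + 1}" for k in range(dataset.N)]
    write_matrix(dataset.Y, expr_path, dataset.gene_ids, sample_ids)
    write_matrix(dataset.X, geno_path, dataset.gene_ids, sample_ids)


def write_truth(model: GRNModel, path_prefix: str | Path) -> tuple[str, str]:
    """Write the generating B and F matrices as `<prefix>.B.tsv` / `<prefix>.F.tsv`."""
    ids = [f"g{i + 1}" for i in range(model.m)]
    b_path, f_path = f"{path_prefix}.B.tsv", f"{path_prefix}.F.tsv"
    write_matrix(model.B, b_path, ids, ids)
    write_matrix(model.F, f_path, ids, ids)
    return b_path, f_path


def read_truth(path_prefix: str | Path) -> GRNModel:
    B = read_matrix(f"{path_prefix}.B.tsv").to_numpy()
    F = read_matrix(f"{path_prefix}.F.tsv").to_numpy()
    return GRNModel(B=B, F=F)


def read_network_matrix(path: str | Path) -> np.ndarray:
    """Read a square coefficient-matrix TSV (gene ids on both axes)."""
    df = read_matrix(path)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {df.shape}")
    return df.to_numpy()


def write_network(
    result: InferenceResult | LRBIResults,
    out_prefix: str | Path,
    formats: tuple[str, ...] = ("matrix", "edges", "sif"),
) -> dict[str, str]:
    """Write the inferred network: full B_hat matrix, edge list, optional SIF.

    The edge list has columns regulator_id, target_id, weight, sign and only
    contains edges surviving the decision threshold; the SIF file
    (``regulator  sign  target``) is readable by standard network viewers.
    """
    if isinstance(result, LRBIResults):
        result = result.as_result()
    ids = result.gene_ids
    written: dict[str, str] = {}
    edges = sorted(result.edges)
    if "matrix" in formats:
        path = f"{out_prefix}.Bhat.tsv"
        write_matrix(result.B_hat, path, ids, ids)
        written["matrix"] = path
    if "edges" in formats:
        path = f"{out_prefix}.edges.tsv"
        with open(path, "w") as fh:
            fh.write("regulator_id\ttarget_id\tweight\tsign\n")
            for i, j, w in edges:
                sign = "+" if w >= 0 else "-"
                fh.write(f"{ids[j]}\t{ids[i]}\t{w!r}\t{sign}\n")
        written["edges"] = path
    if "sif" in formats:
        path = f"{out_prefix}.sif"
        with open(path, "w") as fh:
            for i, j, w in edges:
                fh.write(f"{ids[j]}\t{'+' if w >= 0 else '-'}\t{ids[i]}\n")
        written["sif"] = path
    return written
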