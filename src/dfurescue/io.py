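"""Readers and writers for the on-disk formats of the pipeline.

The expression bundle is the dominant scRNA-seq interchange dialect:
a Matrix Market coordinate file (genes as rows, cells as columns,
1-based indices) with one-ID-per-line ``genes.tsv`` / ``cells.tsv``
sidecars and a tab-separated per-cell metadata table.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .data import (
    FormatError,
    GeneSet,
    LabeledExpression,
    LRPair,
    REQUIRED_META,
    ValidationError,
)

MATRIX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
CELLS_FILE = "cells.tsv"
META_FILE = "meta.tsv"


# ----------------------------------------------------------------- bundle
def read_labeled_expression(
    matrix_path, genes_path, cells_path, meta_path
) -> LabeledExpression:
    """Load and validate an expression bundle from its four files."""
    try:
        counts = sp.csr_matrix(spio.mmread(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad MTX
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    gene_ids = _read_id_list(genes_path)
    cell_ids = _read_id_list(cells_path)
    if counts.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix is {counts.shape} but sidecars list "
            f"{len(gene_ids)} genes and {len(cell_ids)} cells"
        )
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise FormatError("metadata table lacks a cell_id column")
    missing_cols = [c for c in REQUIRED_META if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata table lacks columns: {missing_cols}")
    meta = meta.set_index("cell_id")
    if counts.nnz and np.any(counts.data != np.round(counts.data)):
        raise FormatError("count matrix contains non-integer values")
    counts = counts.astype(np.int64)
    return LabeledExpression(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, meta=meta)


def read_bundle(directory) -> LabeledExpression:
    """Load a bundle written by :func:`write_labeled_expression`."""
    d = str(directory)
    return read_labeled_expression(
        os.path.join(d, MATRIX_FILE),
        os.path.join(d, GENES_FILE),
        os.path.join(d, CELLS_FILE),
        os.path.join(d, META_FILE),
    )


def write_labeled_expression(expr: LabeledExpression, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    d = str(directory)
    spio.mmwrite(os.path.join(d, MATRIX_FILE), expr.counts.tocoo(), field="integer")
    _write_id_list(os.path.join(d, GENES_FILE), expr.gene_ids)
    _write_id_list(os.path.join(d, CELLS_FILE), expr.cell_ids)
    expr.meta.rename_axis("cell_id").reset_index().to_csv(
        os.path.join(d, META_FILE), sep="\t", index=False
    )


def _read_id_list(path) -> np.ndarray:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise FormatError(f"empty identifier list: {path}")
    return np.asarray(ids, dtype=object)


def _write_id_list(path, ids) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# -------------------------------------------------------------------- GMT
def read_gmt(path) -> list[GeneSet]:
    """Parse a tab-separated GMT file (name, description, members...).

    Duplicate members within a set are deduplicated preserving order.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = tuple(dict.fromkeys(members))
            if not deduped:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, description=desc, members=deduped))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ------------------------------------------------------------ LR database
LR_COLUMNS = ("pair_name", "pathway", "ligand_genes", "receptor_genes")


def read_lr_database(path) -> list[LRPair]:
    """Read a ligand-receptor table (CSV; ';'-separated multi-gene fields).

    Gene symbols are uppercased; receptor subunit order is preserved.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in LR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"LR database lacks columns: {missing}")
    pairs: list[LRPair] = []
    for row in df.itertuples(index=False):
        lig = _split_genes(row.ligand_genes)
        rec = _split_genes(row.receptor_genes)
        if not lig:
            raise FormatError(f"LR pair {row.pair_name!r}: empty ligand field")
        if not rec:
            raise FormatError(f"LR pair {row.pair_name!r}: empty receptor field")
        pairs.append(
            LRPair(
                name=str(row.pair_name),
                pathway=str(row.pathway),
                ligand_genes=lig,
                receptor_subunits=rec,
            )
        )
    return pairs


def write_lr_database(pairs: list[LRPair], path) -> None:
    pd.DataFrame(
        {
            "pair_name": [p.name for p in pairs],
            "pathway": [p.pathway for p in pairs],
            "ligand_genes": [";".join(p.ligand_genes) for p in pairs],
            "receptor_genes": [";".join(p.receptor_subunits) for p in pairs],
        }
    ).to_csv(path, index=False)


def _split_genes(raw) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ()
    return tuple(g.strip().upper() for g in str(raw).split(";") if g.strip())


# ------------------------------------------------------------ trend series
def read_trend_series(path) -> pd.DataFrame:
    """Gene × timepoint TSV of mean expression; column order = time order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise FormatError("trend series needs at least two timepoint columns")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValidationError("trend series contains non-finite values")
    return df.astype(float)


def write_trend_series(series: pd.DataFrame, path) -> None:
    series.rename_axis("gene").to_csv(path, sep="\t")
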