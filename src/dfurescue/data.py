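"""Core containers for the three-state wound-healing analysis.

The analysis compares three clinical states of diabetic foot skin/blood:
``DS`` (diabetic skin, no ulcer), ``DFUNH`` (non-healing ulcer) and ``DFUH``
(healing ulcer).  Every downstream contrast is defined on this closed triple,
so unknown group labels are rejected at construction time rather than being
passed through silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: The closed clinical-group vocabulary, in pseudo-trajectory order.
GROUPS = ("DS", "DFUNH", "DFUH")
#: Tissues profiled in the cohort design being emulated.
TISSUES = ("skin", "blood")
#: Metadata columns every cell record must carry.
REQUIRED_META = ("sample_id", "group", "tissue", "cell_type")


class FormatError(ValueError):
    """An on-disk artifact does not conform to its expected format."""


class ValidationError(ValueError):
    """In-memory data violates a structural invariant."""


class ConfigError(ValueError):
    """A configuration value is inconsistent or out of range."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (one GMT line)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor pair; receptors may be multi-subunit complexes."""

    name: str
    pathway: str
    ligand_genes: tuple[str, ...]
    receptor_subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ligand_genes:
            raise ValidationError(f"LR pair {self.name!r} has no ligand genes")
        if not self.receptor_subunits:
            raise ValidationError(f"LR pair {self.name!r} has no receptor subunits")


@dataclass
class LabeledExpression:
    """Sparse gene×cell UMI counts with per-cell clinical metadata.

    Parameters
    ----------
    counts
        Non-negative integer UMI matrix, genes as rows, cells as columns.
    gene_ids, cell_ids
        Ordered unique identifiers matching the matrix dimensions.
    meta
        Per-cell records indexed by cell id with columns ``sample_id``,
        ``group``, ``tissue``, ``cell_type`` and optionally ``subcluster``.
    norm
        Optional normalized layer of identical shape (natural-log scale,
        all values >= 0); produced by :func:`dfurescue.qc.normalize`.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    meta: pd.DataFrame
    norm: sp.csr_matrix | None = None
    _gene_pos: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for label, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {label} identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts contain negative values")

        missing = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata lacks required columns: {missing}")
        absent = [c for c in self.cell_ids if c not in self.meta.index]
        if absent:
            raise ValidationError(
                f"{len(absent)} cell(s) in matrix absent from metadata: "
                + ", ".join(map(str, absent[:10]))
            )
        if self.meta.index.has_duplicates:
            dupes = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate metadata records for cells: {dupes[:10]}")
        # align metadata to matrix column order; extra rows are dropped
        self.meta = self.meta.loc[list(self.cell_ids)].copy()

        bad_groups = set(self.meta["group"]) - set(GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
        bad_tissues = set(self.meta["tissue"]) - set(TISSUES)
        if bad_tissues:
            raise ValidationError(f"unknown tissue labels: {sorted(bad_tissues)}")

        if self.norm is not None:
            self.norm = sp.csr_matrix(self.norm)
            if self.norm.shape != self.counts.shape:
                raise ValidationError("norm layer shape differs from counts")
            if self.norm.nnz and self.norm.data.min() < 0:
                raise ValidationError("norm layer contains negative values")

        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_positions(self, genes, missing: str = "error") -> np.ndarray:
        """Row indices of ``genes``; ``missing`` is 'error' or 'drop'."""
        pos = [self._gene_pos.get(g, -1) for g in genes]
        if missing == "error":
            absent = [g for g, p in zip(genes, pos) if p < 0]
            if absent:
                raise KeyError(f"genes not in matrix: {absent[:10]}")
            return np.asarray(pos)
        return np.asarray([p for p in pos if p >= 0])

    def cells_where(
        self,
        group: str | None = None,
        tissue: str | None = None,
        cell_type: str | None = None,
        subcluster: str | None = None,
        sample_id: str | None = None,
    ) -> np.ndarray:
        """Boolean mask over cells matching every given metadata condition."""
        mask = np.ones(self.n_cells, dtype=bool)
        for col, val in (
            ("group", group),
            ("tissue", tissue),
            ("cell_type", cell_type),
            ("subcluster", subcluster),
            ("sample_id", sample_id),
        ):
            if val is not None:
                if col not in self.meta.columns:
                    raise KeyError(f"metadata has no column {col!r}")
                mask &= (self.meta[col] == val).to_numpy()
        return mask

    def subset_cells(self, mask: np.ndarray) -> "LabeledExpression":
        """New container restricted to the cells selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_cells,):
            raise ValidationError("cell mask has wrong length")
        idx = np.flatnonzero(mask)
        return LabeledExpression(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            meta=self.meta.iloc[idx],
            norm=None if self.norm is None else self.norm[:, idx],
        )

    def norm_values(self, genes=None, cell_mask=None) -> np.ndarray:
        """Dense block of the normalized layer (genes × selected cells)."""
        if self.norm is None:
            raise ValidationError("normalized layer absent; run qc.normalize first")
        mat = self.norm
        if genes is not None:
            mat = mat[self.gene_positions(genes), :]
        if cell_mask is not None:
            mat = mat[:, np.flatnonzero(np.asarray(cell_mask, dtype=bool))]
        return np.asarray(mat.todense())

    def groups_present(self) -> list[str]:
        present = set(self.meta["group"])
        return [g for g in GROUPS if g in present]
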