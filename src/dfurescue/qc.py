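"""Cell-level quality filtering and library-size normalization.

Filtering retains cells with 500–10,000 genes detected and 1,000–100,000
total UMIs (inclusive bounds), mitochondrial UMI fraction < 30% and
hemoglobin UMI fraction < 5% (strict bounds).  Normalization is
log1p-CP10k: ``ln(1 + count * scale / total_umi)`` with ``scale = 1e4``,
which serves the rank tests and group means used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data import ConfigError, LabeledExpression, ValidationError

DEFAULT_HEMO_GENES = ("HBB", "HBA1", "HBA2")


@dataclass
class QCThresholds:
    min_genes: int = 500
    max_genes: int = 10_000
    min_umi: int = 1_000
    max_umi: int = 100_000
    max_mito_frac: float = 0.30
    max_hemo_frac: float = 0.05
    mito_prefix: str = "MT-"
    hemo_genes: tuple[str, ...] = DEFAULT_HEMO_GENES

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ConfigError("need 0 < min_genes < max_genes")
        if not (0 < self.min_umi < self.max_umi):
            raise ConfigError("need 0 < min_umi < max_umi")
        for name in ("max_mito_frac", "max_hemo_frac"):
            frac = getattr(self, name)
            if not 0 < frac <= 1:
                raise ConfigError(f"{name} must lie in (0, 1]")


@dataclass
class QCReport:
    """Per-criterion removal counts; one cell may violate several."""

    n_input: int
    n_retained: int
    n_removed: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": dict(self.n_removed),
        }


def _per_cell_stats(expr: LabeledExpression, thr: QCThresholds):
    counts = expr.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel()
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    gene_ids = np.asarray([str(g) for g in expr.gene_ids])
    mito_rows = np.flatnonzero(
        np.char.startswith(np.char.upper(gene_ids), thr.mito_prefix.upper())
    )
    hemo_set = {g.upper() for g in thr.hemo_genes}
    hemo_rows = np.flatnonzero(np.isin(np.char.upper(gene_ids), sorted(hemo_set)))
    with np.errstate(divide="ignore", invalid="ignore"):
        mito = np.where(
            total > 0, np.asarray(counts[mito_rows].sum(axis=0)).ravel() / np.maximum(total, 1), 0.0
        )
        hemo = np.where(
            total > 0, np.asarray(counts[hemo_rows].sum(axis=0)).ravel() / np.maximum(total, 1), 0.0
        )
    return total, detected, mito, hemo


def filter_cells(
    expr: LabeledExpression, thr: QCThresholds | None = None
) -> tuple[LabeledExpression, QCReport]:
    """Apply all QC criteria at once and report per-criterion removals."""
    thr = thr or QCThresholds()
    total, detected, mito, hemo = _per_cell_stats(expr, thr)

    fails = {
        "low_genes": detected < thr.min_genes,
        "high_genes": detected > thr.max_genes,
        "low_umi": total < thr.min_umi,
        "high_umi": total > thr.max_umi,
        "mito_frac": mito >= thr.max_mito_frac,
        "hemo_frac": hemo >= thr.max_hemo_frac,
    }
    keep = ~np.logical_or.reduce(list(fails.values()))
    if not keep.any():
        raise ValidationError("all cells removed by QC filtering")
    report = QCReport(
        n_input=expr.n_cells,
        n_retained=int(keep.sum()),
        n_removed={k: int(v.sum()) for k, v in fails.items()},
    )
    return expr.subset_cells(keep), report


def normalize(expr: LabeledExpression, scale: float = 1e4) -> LabeledExpression:
    """Attach the log1p-CP10k layer; raw counts are left untouched.

    norm[g, c] = ln(1 + counts[g, c] * scale / total_umi[c]).  Invariant to
    per-cell count scaling (doubling every count in a cell changes nothing)
    and monotone in counts within a cell.
    """
    counts = expr.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel()
    if (total == 0).any():
        bad = [expr.cell_ids[i] for i in np.flatnonzero(total == 0)[:10]]
        raise ValidationError(f"zero-UMI cell(s) cannot be normalized: {bad}")
    norm = counts.astype(float) @ sp.diags(scale / total)
    norm = norm.log1p().tocsr()
    return LabeledExpression(
        counts=expr.counts,
        gene_ids=expr.gene_ids,
        cell_ids=expr.cell_ids,
        meta=expr.meta,
        norm=norm,
    )
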