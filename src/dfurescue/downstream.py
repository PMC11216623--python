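"""Differentiation scoring and ROC/AUC biomarker screening.

The differentiation score follows the transcriptional-diversity idea:
cells expressing more distinct genes tend to be less differentiated.
Per-cell gene counts drive a gene-counts signature (the mean expression
of the genes most correlated with gene counts), rank-normalized to
[0, 1]; higher = less differentiated.  ROC screening uses the
Mann-Whitney identity AUC = U / (n_pos * n_neg) with ties counted 1/2,
flagging biomarkers at AUC > 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import LabeledExpression, ValidationError


@dataclass
class CytotraceResult:
    scores: pd.Series                      # per-cell, in [0, 1]
    signature_genes: list[str]
    degenerate: bool = False
    subcluster_medians: pd.Series | None = None
    subcluster_order: list[str] = field(default_factory=list)


def cytotrace_score(
    expr: LabeledExpression,
    n_top: int = 200,
    by: str = "subcluster",
    min_cells: int = 50,
) -> CytotraceResult:
    """Rank-normalized differentiation-potential score per cell.

    gene_counts[c] is the number of genes detected in cell c; the
    signature is the ``n_top`` genes whose normalized expression best
    correlates with gene counts across cells, and the score is the rank
    of the mean signature expression, scaled to [0, 1].  When a
    grouping column is present, groups are ordered by descending median
    score (earlier = less differentiated).
    """
    if expr.norm is None:
        raise ValidationError("normalized layer required for differentiation scoring")
    if expr.n_cells < min_cells:
        raise ValidationError(f"need at least {min_cells} cells")
    gene_counts = np.asarray((expr.counts > 0).sum(axis=0)).ravel().astype(float)
    cells = list(expr.cell_ids)
    if np.ptp(gene_counts) == 0:
        scores = pd.Series(0.5, index=cells)
        return _with_groups(
            CytotraceResult(scores=scores, signature_genes=[], degenerate=True), expr, by
        )

    X = np.asarray(expr.norm.todense(), dtype=float)
    gc = gene_counts - gene_counts.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    num = Xc @ gc
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(gc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, -np.inf)  # flat genes never selected
    top = np.argsort(-r, kind="stable")[:n_top]
    gcs = X[top].mean(axis=0)
    ranks = stats.rankdata(gcs, method="average") - 1.0
    scores = pd.Series(ranks / (len(cells) - 1), index=cells)
    result = CytotraceResult(
        scores=scores, signature_genes=[str(expr.gene_ids[i]) for i in top]
    )
    return _with_groups(result, expr, by)


def _with_groups(result: CytotraceResult, expr: LabeledExpression, by: str) -> CytotraceResult:
    if by in expr.meta.columns and expr.meta[by].notna().any():
        medians = result.scores.groupby(expr.meta[by]).median()
        result.subcluster_medians = medians
        result.subcluster_order = list(medians.sort_values(ascending=False).index)
    return result


# -------------------------------------------------------------------- ROC
@dataclass
class RocResult:
    feature: str
    auc: float
    n_pos: int
    n_neg: int
    biomarker: bool
    auto_oriented: bool = False


def roc_auc(
    values,
    labels,
    positive=None,
    feature: str = "",
    auc_thr: float = 0.7,
) -> RocResult:
    """AUC via the Mann-Whitney identity, with ties counted one half.

    If ``positive`` is not given, the class with the higher mean value is
    treated as positive (so the default AUC is >= 0.5) and the result is
    flagged as auto-oriented.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {list(classes)}")
    auto = positive is None
    if auto:
        means = {c: values[labels == c].mean() for c in classes}
        positive = max(classes, key=lambda c: means[c])
    pos_mask = labels == positive
    n_pos, n_neg = int(pos_mask.sum()), int((~pos_mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("one class is empty")
    ranks = stats.rankdata(values, method="average")
    u = ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    return RocResult(
        feature=feature,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        biomarker=auc > auc_thr,
        auto_oriented=auto,
    )


def roc_screen(
    features: pd.DataFrame, labels, positive=None, auc_thr: float = 0.7
) -> pd.DataFrame:
    """Screen a feature × sample table; one ROC result per feature row."""
    results = [
        roc_auc(features.loc[f], labels, positive=positive, feature=f, auc_thr=auc_thr)
        for f in features.index
    ]
    return pd.DataFrame(
        {
            "auc": [r.auc for r in results],
            "n_pos": [r.n_pos for r in results],
            "n_neg": [r.n_neg for r in results],
            "biomarker": [r.biomarker for r in results],
            "auto_oriented": [r.auto_oriented for r in results],
        },
        index=list(features.index),
    )
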