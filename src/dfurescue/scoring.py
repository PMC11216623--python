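"""Gene-set activity: control-binned module scores and preranked GSEA.

The module score is the per-cell mean expression of a gene set minus the
mean of expression-bin-matched control genes, so a positive score means
the set is active above the cell's background.  Preranked GSEA walks the
metric-sorted gene list with a weighted running sum; significance comes
from a gene-label permutation null, with NES scaling by the mean
magnitude of same-sign null scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneSet, LabeledExpression, ValidationError
from .differential import bh_adjust


# ------------------------------------------------------------ module score
def module_score(
    expr: LabeledExpression,
    gene_set: GeneSet,
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Control-binned per-cell activity score for one gene set.

    Genes are split into ``nbin`` equal-size bins by mean expression
    across cells; each member gene contributes ``nctrl`` control genes
    drawn with replacement from its bin.  Score = mean member expression
    - mean control expression, per cell.
    """
    if expr.norm is None:
        raise ValidationError("normalized layer required for module scoring")
    if expr.n_genes < nbin:
        raise ValidationError(f"need at least nbin={nbin} genes")
    members = expr.gene_positions(gene_set.members, missing="drop")
    if members.size == 0:
        raise ValidationError(f"no member of {gene_set.name!r} present in the matrix")

    norm = expr.norm.tocsr()
    avg = np.asarray(norm.mean(axis=1)).ravel()
    order = np.argsort(avg, kind="stable")
    bins = np.array_split(order, nbin)
    bin_of = np.empty(expr.n_genes, dtype=int)
    for b, rows in enumerate(bins):
        bin_of[rows] = b

    rng = np.random.default_rng(seed)
    ctrl_rows = np.concatenate(
        [rng.choice(bins[bin_of[g]], size=nctrl, replace=True) for g in members]
    )
    member_mean = np.asarray(norm[members].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(norm[ctrl_rows].mean(axis=0)).ravel()
    return pd.Series(member_mean - ctrl_mean, index=list(expr.cell_ids), name=gene_set.name)


# ------------------------------------------------------------------- GSEA
@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p: float
    n_hits: int
    p_adj: float | None = None
    significant: bool | None = None


def enrichment_score(metric: np.ndarray, hit_mask: np.ndarray, weight_p: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov-style enrichment score in [-1, 1].

    ``metric`` must already be sorted in decreasing order; ``hit_mask``
    marks set members along that order.
    """
    n = len(metric)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValidationError("gene set must hit a strict subset of the ranked list")
    w = np.abs(metric) ** weight_p
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member metrics are zero: fall back to equal weights
        hit_w = hit_mask.astype(float)
        denom = float(n_hits)
    running = np.cumsum(hit_w / denom - np.where(hit_mask, 0.0, 1.0 / (n - n_hits)))
    es = float(running[np.argmax(np.abs(running))])
    return float(np.clip(es, -1.0, 1.0))  # guard rounding at the extremes


def gsea_preranked(
    ranked: pd.Series,
    gene_set: GeneSet,
    weight_p: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA for one gene set against a gene -> metric ranking.

    The null permutes gene labels (random member positions of the same
    size); p is the one-sided tail of same-sign null scores with the +1
    correction, and NES divides ES by the mean |null ES| of its sign.
    """
    metric = ranked.to_numpy(dtype=float)
    if not np.isfinite(metric).all():
        raise ValidationError("ranking metric contains non-finite values")
    order = np.argsort(-metric, kind="stable")
    metric = metric[order]
    genes = np.asarray(ranked.index, dtype=object)[order]
    hit_mask = np.isin(genes, list(gene_set.members))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValidationError(f"no member of {gene_set.name!r} in the ranked list")
    es = enrichment_score(metric, hit_mask, weight_p)

    rng = np.random.default_rng(seed)
    null = np.empty(nperm)
    n = len(metric)
    for i in range(nperm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hits, replace=False)] = True
        null[i] = enrichment_score(metric, mask, weight_p)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        nes, p = 0.0, 1.0
    else:
        nes = es / np.abs(same_sign).mean()
        p = (1.0 + float((np.abs(same_sign) >= abs(es)).sum())) / (1.0 + same_sign.size)
    return GseaResult(name=gene_set.name, es=es, nes=float(nes), p=float(p), n_hits=n_hits)


def gsea_collection(
    ranked: pd.Series,
    gene_sets: list[GeneSet],
    weight_p: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
    adjp_thr: float = 0.05,
    nes_min: float = 1.0,
) -> pd.DataFrame:
    """GSEA over a set collection with BH adjustment across sets.

    Significance requires adjusted p < ``adjp_thr`` and |NES| >= ``nes_min``.
    """
    results = [
        gsea_preranked(ranked, gs, weight_p=weight_p, nperm=nperm, seed=seed + i)
        for i, gs in enumerate(gene_sets)
    ]
    df = pd.DataFrame(
        {
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "n_hits": [r.n_hits for r in results],
        },
        index=[r.name for r in results],
    )
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["p_adj"] < adjp_thr) & (df["nes"].abs() >= nes_min)
    return df


def preranked_input_from_de(
    de: pd.DataFrame, adjp_thr: float = 0.05, logfc_thr: float = 0.5
) -> pd.Series:
    """DE-derived ranking metric for single-cell GSEA input.

    Genes are pre-filtered at adjusted p < 0.05 and |avg log2FC| > 0.5
    before ranking by log2 fold change.
    """
    sel = (de["p_adj"] < adjp_thr) & (de["log2fc"].abs() > logfc_thr)
    if not sel.any():
        raise ValidationError("no genes pass the GSEA pre-filter")
    return de.loc[sel, "log2fc"].sort_values(ascending=False)
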