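"""Ligand-receptor communication scoring and rescue classification.

The per-group communication probability of an edge (sender cell type,
receiver cell type, LR pair) follows the mass-action/Hill form

    prob = L*R / (Kh + L*R),   Kh = 0.5,

with L the Tukey trimean of ligand expression in the sender (geometric
mean over multiple ligand genes) and R the geometric mean over receptor
subunits of their trimeans in the receiver.  Differential edges require
both ligand and receptor log2FC beyond +-0.2 (inclusive) in the
sender/receiver cell types; a rescue edge reverses class across the two
contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import LabeledExpression, LRPair, ValidationError


def trimean(x: np.ndarray) -> float:
    """Tukey's trimean (Q1 + 2*Q2 + Q3) / 4, a robust location estimate."""
    q1, q2, q3 = np.percentile(np.asarray(x, float), [25, 50, 75])
    return float((q1 + 2 * q2 + q3) / 4)


def _group_expression(values: np.ndarray, method: str) -> float:
    return trimean(values) if method == "trimean" else float(np.mean(values))


def _geomean(vals) -> float:
    vals = np.asarray(vals, dtype=float)
    if (vals <= 0).any():
        return 0.0
    return float(np.exp(np.log(vals).mean()))


def comm_prob(
    expr: LabeledExpression,
    lr_db: list[LRPair],
    group: str,
    kh: float = 0.5,
    method: str = "trimean",
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Communication probability for every edge of one clinical group.

    Edges whose ligand or receptor genes are absent from the matrix are
    skipped with a warning rather than raising.
    """
    if expr.norm is None:
        raise ValidationError("normalized layer required for communication scoring")
    if method not in ("trimean", "mean"):
        raise ValidationError(f"unknown expression summary {method!r}")
    meta = expr.meta
    in_group = meta["group"] == group
    types = cell_types or sorted(meta.loc[in_group, "cell_type"].unique())

    # summarize every needed gene once per cell type
    needed = sorted({g for p in lr_db for g in (*p.ligand_genes, *p.receptor_subunits)})
    present = [g for g in needed if g in set(expr.gene_ids)]
    skipped = set(needed) - set(present)
    if skipped:
        warnings.warn(
            f"{len(skipped)} LR gene(s) absent from matrix; affected edges skipped",
            stacklevel=2,
        )
    summary: dict[str, dict[str, float]] = {}
    for ct in types:
        mask = expr.cells_where(group=group, cell_type=ct)
        if not mask.any():
            continue
        block = expr.norm_values(genes=present, cell_mask=mask)
        summary[ct] = {
            g: _group_expression(block[i], method) for i, g in enumerate(present)
        }

    rows = []
    for pair in lr_db:
        if any(g in skipped for g in (*pair.ligand_genes, *pair.receptor_subunits)):
            continue
        for sender, s_expr in summary.items():
            L = _geomean([s_expr[g] for g in pair.ligand_genes])
            for receiver, r_expr in summary.items():
                R = _geomean([r_expr[g] for g in pair.receptor_subunits])
                lr = L * R
                rows.append(
                    {
                        "sender": sender,
                        "receiver": receiver,
                        "pair": pair.name,
                        "pathway": pair.pathway,
                        "L": L,
                        "R": R,
                        "prob": lr / (kh + lr),
                    }
                )
    return pd.DataFrame(
        rows, columns=["sender", "receiver", "pair", "pathway", "L", "R", "prob"]
    )


def diff_lr(
    edges: pd.DataFrame,
    lr_db: list[LRPair],
    de_by_celltype: dict[str, pd.DataFrame],
    thr: float = 0.2,
) -> pd.DataFrame:
    """Classify each edge as up / down / none for one contrast.

    ``de_by_celltype`` holds the differential tables of *eligible* cell
    types for the contrast; an edge whose sender or receiver type is not
    eligible, or whose genes lack statistics, stays unclassified
    (class "none", flag set).  Up requires ligand and receptor log2FC
    >= thr; down requires both <= -thr (boundaries inclusive).
    """
    pairs = {p.name: p for p in lr_db}
    out = edges.drop_duplicates(subset=["sender", "receiver", "pair"]).copy()
    lig_fc, rec_fc, classes, flags = [], [], [], []
    for row in out.itertuples(index=False):
        pair = pairs[row.pair]
        lfc = _gene_fc(de_by_celltype, row.sender, pair.ligand_genes)
        rfc = _gene_fc(de_by_celltype, row.receiver, pair.receptor_subunits)
        lig_fc.append(lfc)
        rec_fc.append(rfc)
        if np.isnan(lfc) or np.isnan(rfc):
            classes.append("none")
            flags.append(True)
        elif lfc >= thr and rfc >= thr:
            classes.append("up")
            flags.append(False)
        elif lfc <= -thr and rfc <= -thr:
            classes.append("down")
            flags.append(False)
        else:
            classes.append("none")
            flags.append(False)
    out["ligand_log2fc"] = lig_fc
    out["receptor_log2fc"] = rec_fc
    out["diff_class"] = classes
    out["missing_stats"] = flags
    return out


def _gene_fc(de_by_celltype, cell_type, genes) -> float:
    """Mean log2FC of the genes within one cell type; NaN if unavailable."""
    de = de_by_celltype.get(cell_type)
    if de is None:
        return float("nan")
    try:
        return float(np.mean([de.loc[g, "log2fc"] for g in genes]))
    except KeyError:
        return float("nan")


def rescue_lr(diff_unhealing: pd.DataFrame, diff_healing: pd.DataFrame) -> pd.DataFrame:
    """Combine the two contrasts into rescue classes per edge.

    rescue_up: down in the unhealing contrast and up in the healing one;
    rescue_down: the reverse order.  Everything else is "none".
    """
    key = ["sender", "receiver", "pair"]
    merged = diff_unhealing[key + ["pathway", "diff_class"]].merge(
        diff_healing[key + ["diff_class"]],
        on=key,
        how="inner",
        suffixes=("_unhealing", "_healing"),
    )
    if len(merged) != len(diff_unhealing) or len(merged) != len(diff_healing):
        raise ValidationError("contrasts classified on different edge universes")

    def _cls(row):
        u, h = row["diff_class_unhealing"], row["diff_class_healing"]
        if u == "down" and h == "up":
            return "rescue_up"
        if u == "up" and h == "down":
            return "rescue_down"
        return "none"

    merged["rescue_class"] = merged.apply(_cls, axis=1)
    return merged


def pathway_summary(edges: pd.DataFrame) -> pd.DataFrame:
    """Edge counts and summed probability ("strength") per pathway."""
    return (
        edges.groupby("pathway")
        .agg(n_edges=("prob", "size"), strength=("prob", "sum"))
        .sort_values("strength", ascending=False)
    )
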