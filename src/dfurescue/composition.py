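"""Cell-type composition analysis across the three clinical states.

A "rescue" cell type changes proportion from DS to DFUNH and reverses
from DFUNH to DFUH, with both log2 fold changes exceeding 0.1 in
magnitude.  Per-sample proportions feed a Welch t-test for abundance
significance at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GROUPS, LabeledExpression, ValidationError


@dataclass
class ProportionTable:
    """Group-level and per-sample proportions for one labeling level."""

    by: str
    group_props: pd.DataFrame      # entity x group, columns sum to 1
    sample_props: pd.DataFrame     # long: sample_id, group, entity, proportion

    def entities(self) -> list[str]:
        return list(self.group_props.index)


@dataclass
class RescueRecord:
    """Rescue classification of one entity across the two contrasts."""

    entity: str
    l1: float                      # log2 (DFUNH / DS)
    l2: float                      # log2 (DFUH / DFUNH)
    rescue_class: str              # rescue_up | rescue_down | none
    degenerate: bool = False
    p_unhealing: float | None = None
    p_healing: float | None = None


def proportions(expr: LabeledExpression, by: str = "cell_type") -> ProportionTable:
    """Entity proportions per group and per sample.

    Group proportions divide entity cell counts by the total cells of the
    group, so each group column sums to one; an entity missing from a
    group gets proportion zero.
    """
    if by not in expr.meta.columns:
        raise ValidationError(f"metadata has no labeling column {by!r}")
    meta = expr.meta
    present = expr.groups_present()
    for g in present:
        if (meta["group"] == g).sum() == 0:
            raise ValidationError(f"group {g!r} has zero cells")
    entities = sorted(meta[by].dropna().unique())

    counts = (
        meta.groupby(["group", by], observed=True).size().unstack(fill_value=0)
    ).reindex(index=present, columns=entities, fill_value=0)
    group_props = (counts.T / counts.sum(axis=1)).loc[entities, present]

    sample_counts = (
        meta.groupby(["sample_id", by], observed=True).size().unstack(fill_value=0)
    ).reindex(columns=entities, fill_value=0)
    sample_totals = sample_counts.sum(axis=1)
    sample_group = meta.groupby("sample_id")["group"].first()
    long = (
        (sample_counts.T / sample_totals)
        .T.rename_axis("sample_id")
        .reset_index()
        .melt(id_vars="sample_id", var_name="entity", value_name="proportion")
    )
    long["group"] = long["sample_id"].map(sample_group)
    return ProportionTable(by=by, group_props=group_props, sample_props=long)


def classify_rescue(
    p_ds: float,
    p_nh: float,
    p_h: float,
    thr: float = 0.1,
    eps: float = 1e-12,
) -> RescueRecord:
    """Classify a rescue entity from its three group proportions.

    ``eps`` is a Haldane-style pseudo-proportion guarding log2 of zero
    (use 0.5 / N_group when proportions come from N_group cells).
    rescue_up: l1 < -thr and l2 > thr; rescue_down: the mirror image.
    """
    if min(p_ds, p_nh, p_h) < 0:
        raise ValidationError("proportions must be non-negative")
    if eps <= 0:
        raise ValidationError("eps must be positive")
    degenerate = min(p_ds, p_nh, p_h) == 0
    l1 = float(np.log2((p_nh + eps) / (p_ds + eps)))
    l2 = float(np.log2((p_h + eps) / (p_nh + eps)))
    if l1 < -thr and l2 > thr:
        cls = "rescue_up"
    elif l1 > thr and l2 < -thr:
        cls = "rescue_down"
    else:
        cls = "none"
    return RescueRecord(entity="", l1=l1, l2=l2, rescue_class=cls, degenerate=degenerate)


def rescue_cell_types(
    table: ProportionTable,
    thr: float = 0.1,
    group_sizes: dict | None = None,
) -> list[RescueRecord]:
    """Classify every entity of a proportion table, with abundance tests."""
    props = table.group_props
    missing = [g for g in GROUPS if g not in props.columns]
    if missing:
        raise ValidationError(f"groups absent from proportion table: {missing}")
    eps_by_group = {
        g: 0.5 / group_sizes[g] if group_sizes else 1e-12 for g in GROUPS
    }
    eps = min(eps_by_group.values())
    records = []
    for entity, row in props.iterrows():
        rec = classify_rescue(row["DS"], row["DFUNH"], row["DFUH"], thr=thr, eps=eps)
        rec.entity = entity
        rec.p_unhealing = abundance_test(table, entity, ("DS", "DFUNH"))
        rec.p_healing = abundance_test(table, entity, ("DFUNH", "DFUH"))
        records.append(rec)
    return records


def abundance_test(table: ProportionTable, entity: str, groups: tuple) -> float:
    """Welch two-sample t-test on per-sample proportions of one entity.

    Degenerate cases follow fixed rules rather than raising: identical
    zero-variance samples give p = 1; fewer than two samples in either
    group gives NaN (undefined, flagged by the caller).
    """
    long = table.sample_props
    a = long.loc[(long["group"] == groups[0]) & (long["entity"] == entity), "proportion"]
    b = long.loc[(long["group"] == groups[1]) & (long["entity"] == entity), "proportion"]
    a, b = a.to_numpy(float), b.to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-identical samples
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def phenotype_ratio(
    expr: LabeledExpression, numerator_type: str, denominator_type: str
) -> dict[str, float]:
    """Per-group cell-count ratio of two cell types (e.g. M1/M2).

    A group lacking the denominator type yields NaN (undefined flag).
    """
    out = {}
    for g in expr.groups_present():
        num = int((expr.cells_where(group=g, cell_type=numerator_type)).sum())
        den = int((expr.cells_where(group=g, cell_type=denominator_type)).sum())
        out[g] = num / den if den > 0 else float("nan")
    return out
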