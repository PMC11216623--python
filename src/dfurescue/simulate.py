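"""Synthetic labeled single-cell cohorts with planted, manifest-recorded effects.

The generator emulates the statistical structure of a three-group diabetic
wound cohort (DS / DFUNH / DFUH):

* negative-binomial UMI counts with gene-level dispersion and log-normal
  baseline means scaled to ~2,000 UMI per cell;
* cell-type identity expressed through marker genes at 5x baseline;
* group-dependent cell-type proportion shifts (a fibroblast-like type that
  collapses in non-healing wounds and recovers in healing wounds, and an
  M1/M2-like ratio reversal);
* "rescue" genes whose mean drops 2-fold from DS to DFUNH and recovers
  2-fold from DFUNH to DFUH (and the mirrored up-then-down pattern);
* ligand-receptor pairs whose sender-ligand and receiver-receptor
  expression reverse across the two contrasts;
* short mean-expression series with planted monotone/reversing trends.

Every planted effect is recorded in a :class:`TruthManifest` so each
pipeline stage can be scored for parameter recovery without any download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import ConfigError, GROUPS, LabeledExpression, LRPair, ValidationError

DEFAULT_CELL_TYPES = (
    "Fibro",
    "BasalKera",
    "DiffKera",
    "VasEndo",
    "T_lympho",
    "M1",
    "M2",
    "SMC",
)

# Group-wise cell-type proportion vectors over DEFAULT_CELL_TYPES.
# Keratinocytes dominate skin tissue (DiffKera is the largest, stable
# compartment); Fibro is planted as a rescue-up composition shift
# (0.20 -> 0.10 -> 0.18) and the M1/M2 pair reverses its ratio
# (1.5 -> 0.55 -> 1.29) so phenotype-ratio recovery is testable.
DEFAULT_PROPORTIONS = {
    "DS": (0.20, 0.12, 0.25, 0.07, 0.10, 0.09, 0.06, 0.11),
    "DFUNH": (0.10, 0.12, 0.25, 0.07, 0.14, 0.06, 0.11, 0.15),
    "DFUH": (0.18, 0.12, 0.25, 0.07, 0.10, 0.09, 0.07, 0.12),
}


# --------------------------------------------------------------- manifest
@dataclass(frozen=True)
class PlantedRescueGene:
    """A gene whose mean reverses across the two contrasts in one cell type.

    ``direction`` is the rescue class: "up" means down in DFUNH then up in
    DFUH.  Folds are multiplicative mean ratios DFUNH/DS and DFUH/DFUNH.
    ``cell_type`` of None plants the effect in every cell type.
    """

    gene: str
    cell_type: str | None
    direction: str
    fold_unhealing: float
    fold_healing: float


@dataclass(frozen=True)
class PlantedShift:
    cell_type: str
    proportions: dict  # group -> proportion


@dataclass(frozen=True)
class PlantedLRReversal:
    pair_name: str
    sender: str
    receiver: str
    direction: str  # rescue class of the pair
    fold_unhealing: float
    fold_healing: float


@dataclass(frozen=True)
class PlantedTrendGene:
    gene: str
    steps: tuple[int, ...]


@dataclass
class TruthManifest:
    """Ground truth emitted by the simulator, for recovery tests."""

    rescue_genes: list[PlantedRescueGene] = field(default_factory=list)
    celltype_shifts: list[PlantedShift] = field(default_factory=list)
    lr_reversals: list[PlantedLRReversal] = field(default_factory=list)
    trend_genes: list[PlantedTrendGene] = field(default_factory=list)
    nb_mean: dict = field(default_factory=dict)  # gene -> baseline mean
    dispersion: float = 0.5
    markers: dict = field(default_factory=dict)  # cell_type -> marker genes
    seed: int = 0

    def validate(self, gene_universe, cell_types) -> None:
        genes = set(gene_universe)
        types = set(cell_types)
        for r in self.rescue_genes:
            if r.gene not in genes:
                raise ConfigError(f"planted gene {r.gene!r} not in universe")
            if r.cell_type is not None and r.cell_type not in types:
                raise ConfigError(f"planted cell type {r.cell_type!r} not in universe")
            if r.fold_unhealing <= 0 or r.fold_healing <= 0:
                raise ConfigError("planted fold changes must be positive")
        by_group: dict[str, float] = {}
        for s in self.celltype_shifts:
            for g, p in s.proportions.items():
                by_group[g] = by_group.get(g, 0.0) + p
        for g, total in by_group.items():
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"group {g} proportions sum to {total}, not 1")

    def to_json(self, path) -> None:
        payload = {
            "rescue_genes": [asdict(r) for r in self.rescue_genes],
            "celltype_shifts": [asdict(s) for s in self.celltype_shifts],
            "lr_reversals": [asdict(r) for r in self.lr_reversals],
            "trend_genes": [asdict(t) for t in self.trend_genes],
            "nb_mean": self.nb_mean,
            "dispersion": self.dispersion,
            "markers": self.markers,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            rescue_genes=[PlantedRescueGene(**r) for r in raw["rescue_genes"]],
            celltype_shifts=[PlantedShift(**s) for s in raw["celltype_shifts"]],
            lr_reversals=[
                PlantedLRReversal(**r) for r in raw["lr_reversals"]
            ],
            trend_genes=[
                PlantedTrendGene(gene=t["gene"], steps=tuple(t["steps"]))
                for t in raw["trend_genes"]
            ],
            nb_mean=raw["nb_mean"],
            dispersion=raw["dispersion"],
            markers={k: list(v) for k, v in raw.get("markers", {}).items()},
            seed=raw["seed"],
        )


# ----------------------------------------------------------------- config
@dataclass
class SimConfig:
    """Study conditions for the cohort generator.

    Defaults mirror a small three-group wound cohort: 3 samples per group,
    200 cells per sample, 1,000 genes over 8 cell types with 5 markers each,
    NB dispersion 0.5, and 20 planted 2-fold rescue genes in the
    fibroblast-like type.
    """

    samples_per_group: tuple[int, int, int] = (3, 3, 3)
    cells_per_sample: int = 200
    n_genes: int = 1000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    markers_per_type: int = 5
    marker_fold: float = 5.0
    dispersion: float = 0.5
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.0
    target_umi: float = 2000.0
    libsize_sdlog: float = 0.3
    tissue: str = "skin"
    proportions: dict | None = None  # group -> vector over cell_types
    rescue_genes: list[PlantedRescueGene] | None = None  # None -> auto-plant
    n_rescue_genes: int = 20
    rescue_fold: float = 2.0
    rescue_cell_type: str | None = "DiffKera"
    planted_quantile: float = 0.90  # plant effects in well-detected genes only
    n_lr_reversals: int = 3
    n_lr_decoys: int = 3
    lr_fold: float = 2.0
    lr_sender: str = "Fibro"
    lr_receiver: str = "BasalKera"

    def __post_init__(self) -> None:
        if self.n_genes < self.markers_per_type * len(self.cell_types):
            raise ConfigError("too few genes to host all marker blocks")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        props = self.proportions or {
            g: DEFAULT_PROPORTIONS[g][: len(self.cell_types)] for g in GROUPS
        }
        self.proportions = {g: np.asarray(v, dtype=float) for g, v in props.items()}
        for g, v in self.proportions.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r} in proportions")
            if len(v) != len(self.cell_types) or abs(v.sum() - 1) > 1e-9 or (v < 0).any():
                raise ConfigError(f"proportions for {g} are not a simplex vector")

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """Conditions with no planted effects (for calibration runs)."""
        n_types = overrides.pop("n_types", len(DEFAULT_CELL_TYPES))
        types = DEFAULT_CELL_TYPES[:n_types]
        uniform = np.full(n_types, 1.0 / n_types)
        defaults = dict(
            cell_types=types,
            proportions={g: uniform for g in GROUPS},
            rescue_genes=[],
            n_rescue_genes=0,
            n_lr_reversals=0,
        )
        defaults.update(overrides)
        return cls(**defaults)


# ----------------------------------------------------------------- cohort
def simulate_cohort(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[LabeledExpression, TruthManifest]:
    """Draw a labeled three-group cohort and its ground-truth manifest.

    Identical (config, seed) pairs yield identical output.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    n_types = len(cfg.cell_types)
    width = max(4, len(str(cfg.n_genes)))
    genes = np.asarray([f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)], dtype=object)

    base = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, cfg.n_genes)
    base *= cfg.target_umi / base.sum()

    # marker blocks: type t owns genes [t*k, (t+1)*k)
    k = cfg.markers_per_type
    markers = {ct: list(genes[t * k : (t + 1) * k]) for t, ct in enumerate(cfg.cell_types)}
    marker_rows = {ct: np.arange(t * k, (t + 1) * k) for t, ct in enumerate(cfg.cell_types)}

    rescue = cfg.rescue_genes
    reserved = set(np.arange(n_types * k))
    if rescue is None:
        rescue = _auto_rescue_genes(cfg, rng, genes, base, reserved)
    for r in rescue:
        reserved.update(np.flatnonzero(genes == r.gene))

    lr_pairs, lr_reversals = _auto_lr_pairs(cfg, rng, genes, base, reserved)

    manifest = TruthManifest(
        rescue_genes=list(rescue),
        celltype_shifts=[
            PlantedShift(
                cell_type=ct,
                proportions={g: float(cfg.proportions[g][t]) for g in GROUPS},
            )
            for t, ct in enumerate(cfg.cell_types)
        ],
        lr_reversals=lr_reversals,
        nb_mean={g: float(m) for g, m in zip(genes, base)},
        dispersion=cfg.dispersion,
        markers=markers,
        seed=int(seed),
    )
    manifest.validate(genes, cfg.cell_types)

    # per-(group, cell type) mean vectors: baseline x marker factor x planted factors
    gene_pos = {g: i for i, g in enumerate(genes)}
    group_factor = {
        (g, ct): np.ones(cfg.n_genes) for g in GROUPS for ct in cfg.cell_types
    }
    planted_effects = list(rescue) + [
        _lr_effect(rev, pair, role)
        for rev, pair in zip(lr_reversals, lr_pairs)
        for role in ("ligand", "receptor")
    ]
    for eff in planted_effects:
        targets = cfg.cell_types if eff.cell_type is None else (eff.cell_type,)
        rows = [gene_pos[g] for g in eff.gene.split(";")]
        for ct in targets:
            for row in rows:
                group_factor[("DFUNH", ct)][row] *= eff.fold_unhealing
                group_factor[("DFUH", ct)][row] *= eff.fold_unhealing * eff.fold_healing

    mu = {}
    for g in GROUPS:
        for t, ct in enumerate(cfg.cell_types):
            vec = base * group_factor[(g, ct)]
            vec = vec.copy()
            vec[marker_rows[ct]] *= cfg.marker_fold
            mu[(g, ct)] = vec

    blocks, cell_rows = [], []
    shape = 1.0 / cfg.dispersion
    for gi, g in enumerate(GROUPS):
        for s in range(cfg.samples_per_group[gi]):
            sample = f"{g}_s{s + 1}"
            type_idx = rng.choice(n_types, size=cfg.cells_per_sample, p=cfg.proportions[g])
            libf = rng.lognormal(0.0, cfg.libsize_sdlog, cfg.cells_per_sample)
            mu_block = np.stack([mu[(g, cfg.cell_types[t])] for t in type_idx], axis=1)
            mu_block *= libf[np.newaxis, :]
            lam = rng.gamma(shape, mu_block * cfg.dispersion)
            blocks.append(sp.csr_matrix(rng.poisson(lam)))
            for t in type_idx:
                cell_rows.append((sample, g, cfg.tissue, cfg.cell_types[t]))

    counts = sp.hstack(blocks, format="csr").astype(np.int64)
    cell_ids = np.asarray([f"C{i + 1:06d}" for i in range(counts.shape[1])], dtype=object)
    meta = pd.DataFrame(
        cell_rows, columns=["sample_id", "group", "tissue", "cell_type"], index=cell_ids
    )
    expr = LabeledExpression(counts=counts, gene_ids=genes, cell_ids=cell_ids, meta=meta)
    expr.lr_pairs = lr_pairs  # convenience attachment for pipeline runs
    return expr, manifest


def _auto_rescue_genes(cfg, rng, genes, base, reserved) -> list[PlantedRescueGene]:
    if cfg.n_rescue_genes == 0:
        return []
    # plant only in detectably expressed genes: a fold change on a gene that
    # is rarely observed at this sequencing depth carries no rank-test signal
    cut = np.quantile(base, cfg.planted_quantile)
    candidates = np.flatnonzero(base >= cut)
    candidates = candidates[~np.isin(candidates, list(reserved))]
    if len(candidates) < cfg.n_rescue_genes:
        raise ConfigError("not enough expressed genes to plant rescue effects")
    chosen = rng.choice(candidates, size=cfg.n_rescue_genes, replace=False)
    out = []
    f = cfg.rescue_fold
    for j, idx in enumerate(chosen):
        up = j < cfg.n_rescue_genes // 2 or cfg.n_rescue_genes == 1
        out.append(
            PlantedRescueGene(
                gene=str(genes[idx]),
                cell_type=cfg.rescue_cell_type,
                direction="up" if up else "down",
                fold_unhealing=1.0 / f if up else f,
                fold_healing=f if up else 1.0 / f,
            )
        )
    return out


def _auto_lr_pairs(cfg, rng, genes, base, reserved):
    n_pairs = cfg.n_lr_reversals + cfg.n_lr_decoys
    if n_pairs == 0:
        return [], []
    n_lig = n_pairs
    n_rec = n_pairs + 1  # first pair gets a two-subunit receptor
    cut = np.quantile(base, cfg.planted_quantile)
    candidates = np.flatnonzero(base >= cut)
    candidates = candidates[~np.isin(candidates, list(reserved))]
    if len(candidates) < n_lig + n_rec:
        raise ConfigError("not enough expressed genes to build LR pairs")
    chosen = rng.choice(candidates, size=n_lig + n_rec, replace=False)
    lig_idx, rec_idx = chosen[:n_lig], chosen[n_lig:]
    pairs, reversals = [], []
    rec_cursor = 0
    for i in range(n_pairs):
        n_sub = 2 if i == 0 else 1
        subunits = tuple(str(genes[r]) for r in rec_idx[rec_cursor : rec_cursor + n_sub])
        rec_cursor += n_sub
        pair = LRPair(
            name=f"{genes[lig_idx[i]]}-{'_'.join(subunits)}",
            pathway=f"PATH{i + 1}",
            ligand_genes=(str(genes[lig_idx[i]]),),
            receptor_subunits=subunits,
        )
        pairs.append(pair)
        if i < cfg.n_lr_reversals:
            up = i % 2 == 0  # alternate rescue_up / rescue_down reversals
            reversals.append(
                PlantedLRReversal(
                    pair_name=pair.name,
                    sender=cfg.lr_sender,
                    receiver=cfg.lr_receiver,
                    direction="up" if up else "down",
                    fold_unhealing=1.0 / cfg.lr_fold if up else cfg.lr_fold,
                    fold_healing=cfg.lr_fold if up else 1.0 / cfg.lr_fold,
                )
            )
    return pairs, reversals


def _lr_effect(rev: PlantedLRReversal, pair: LRPair, role: str) -> PlantedRescueGene:
    """Express one side of an LR reversal as a plantable group effect."""
    genes = pair.ligand_genes if role == "ligand" else pair.receptor_subunits
    return PlantedRescueGene(
        gene=";".join(genes),
        cell_type=rev.sender if role == "ligand" else rev.receiver,
        direction=rev.direction,
        fold_unhealing=rev.fold_unhealing,
        fold_healing=rev.fold_healing,
    )


# ------------------------------------------------------------- pseudobulk
def pseudobulk_means(expr: LabeledExpression, order=None) -> pd.DataFrame:
    """Gene × group matrix of mean normalized expression.

    Columns follow ``order`` (default: the pseudo-trajectory order of the
    groups present).  This is the substrate for trend clustering.
    """
    if expr.norm is None:
        raise ValidationError("normalized layer required for pseudobulk means")
    order = list(order) if order is not None else expr.groups_present()
    cols = {}
    for g in order:
        mask = expr.cells_where(group=g)
        if not mask.any():
            raise ValidationError(f"group {g!r} has no cells")
        cols[g] = np.asarray(expr.norm[:, np.flatnonzero(mask)].mean(axis=1)).ravel()
    return pd.DataFrame(cols, index=list(expr.gene_ids), columns=order)


# ------------------------------------------------------------ trend series
@dataclass
class AcuteSimConfig:
    """Conditions for the acute-wound mean-expression series (4 timepoints)."""

    timepoints: tuple[str, ...] = ("day0", "day1", "day3", "day7")
    n_background: int = 160
    n_rescue_down: int = 20  # up-then-down genes
    n_rescue_up: int = 20    # down-then-up genes
    sigma: float = 0.1
    amplitude: float = 1.0
    gene_prefix: str = "A"


def simulate_trend_series(
    planted: list[PlantedTrendGene],
    n_background: int,
    timepoints,
    sigma: float = 0.1,
    amplitude: float = 1.0,
    seed: int = 0,
    background_prefix: str = "B",
) -> pd.DataFrame:
    """Mean-expression series: planted step patterns plus flat background.

    Each gene's series is ``baseline + amplitude * cumsum(steps) + noise``
    with iid Gaussian noise of SD ``sigma``; background genes are flat.
    """
    rng = np.random.default_rng(seed)
    T = len(tuple(timepoints))
    rows, names = [], []
    for p in planted:
        if len(p.steps) != T - 1:
            raise ConfigError(f"gene {p.gene}: {len(p.steps)} steps for T={T}")
        values = amplitude * np.concatenate([[0.0], np.cumsum(p.steps)])
        rows.append(values)
        names.append(p.gene)
    for i in range(n_background):
        rows.append(np.zeros(T))
        names.append(f"{background_prefix}{i + 1:05d}")
    base = rng.uniform(2.0, 8.0, size=len(rows))
    data = np.asarray(rows) + base[:, None] + rng.normal(0.0, sigma, size=(len(rows), T))
    return pd.DataFrame(data, index=names, columns=list(timepoints))


def simulate_acute_series(
    config: AcuteSimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, list[PlantedTrendGene]]:
    """Acute-wound healing series with planted reversing trends."""
    cfg = config or AcuteSimConfig()
    planted = [
        PlantedTrendGene(gene=f"{cfg.gene_prefix}D{i + 1:04d}", steps=(1, 1, -1))
        for i in range(cfg.n_rescue_down)
    ] + [
        PlantedTrendGene(gene=f"{cfg.gene_prefix}U{i + 1:04d}", steps=(-1, -1, 1))
        for i in range(cfg.n_rescue_up)
    ]
    series = simulate_trend_series(
        planted,
        cfg.n_background,
        cfg.timepoints,
        sigma=cfg.sigma,
        amplitude=cfg.amplitude,
        seed=seed,
        background_prefix=f"{cfg.gene_prefix}B",
    )
    return series, planted


# ----------------------------------------------------- diversity gradient
def diversity_gradient_fixture() -> LabeledExpression:
    """Noiseless transcriptional-diversity gradient for score validation.

    51 cells express the first k genes, k rising 100..150, with two count
    levels chosen so every cell has the same 300-UMI library — the
    gradient lives purely in how many genes are detected, not in depth.
    The 50 threshold genes (rows 100..149) are strictly increasing
    indicators of diversity, so a diversity score over that signature
    must order cells exactly by k.
    """
    n_genes, total = 160, 300
    ks = np.arange(100, 151)
    counts = np.zeros((n_genes, len(ks)), dtype=int)
    for c, k in enumerate(ks):
        r = total - 2 * k  # genes with count 3; the rest of the k genes get 2
        counts[:k, c] = 2
        counts[:r, c] = 3
    genes = np.asarray([f"g{i + 1:03d}" for i in range(n_genes)], dtype=object)
    cells = np.asarray([f"c{i + 1:03d}" for i in range(len(ks))], dtype=object)
    meta = pd.DataFrame(
        {"sample_id": "s1", "group": "DS", "tissue": "skin", "cell_type": "Fibro"},
        index=cells,
    )
    return LabeledExpression(
        counts=sp.csr_matrix(counts), gene_ids=genes, cell_ids=cells, meta=meta
    )


# -------------------------------------------------------------- QC fixture
def simulate_qc_fixture(seed: int = 0, n_cells: int = 100):
    """A 100-cell matrix with exactly 17 planted QC violations.

    Violations against the default thresholds: 4 cells with too few genes
    detected, 3 with too many, 3 under the UMI floor, 2 over the UMI
    ceiling, 3 at mitochondrial fraction >= 30% and 2 at hemoglobin
    fraction >= 5%; the remaining 83 cells pass every criterion.
    """
    rng = np.random.default_rng(seed)
    n_mito = 10
    mito = [f"MT-{i + 1}" for i in range(n_mito)]
    hemo = ["HBB", "HBA1", "HBA2"]
    n_other = 12_000 - len(mito) - len(hemo)
    other = [f"Q{i + 1:05d}" for i in range(n_other)]
    genes = np.asarray(mito + hemo + other, dtype=object)
    other_rows = np.arange(len(mito) + len(hemo), len(genes))
    mito_rows = np.arange(len(mito))
    hemo_rows = np.arange(len(mito), len(mito) + len(hemo))

    planned = (
        ["pass"] * (n_cells - 17)
        + ["low_genes"] * 4
        + ["high_genes"] * 3
        + ["low_umi"] * 3
        + ["high_umi"] * 2
        + ["mito"] * 3
        + ["hemo"] * 2
    )
    rng.shuffle(planned)

    rows, cols, vals = [], [], []

    def add(cell, r, v):
        rows.extend(r)
        cols.extend([cell] * len(r))
        vals.extend(v)

    for c, kind in enumerate(planned):
        if kind == "low_genes":
            r = rng.choice(other_rows, 300, replace=False)
            add(c, r, np.full(300, 4))  # 1200 UMIs, within range
        elif kind == "high_genes":
            r = rng.choice(other_rows, 10_500, replace=False)
            add(c, r, np.full(10_500, 2))  # 21,000 UMIs, within range
        elif kind == "low_umi":
            r = rng.choice(other_rows, 600, replace=False)
            add(c, r, np.ones(600, dtype=int))  # 600 UMIs
        elif kind == "high_umi":
            r = rng.choice(other_rows, 600, replace=False)
            add(c, r, np.full(600, 250))  # 150,000 UMIs
        elif kind == "mito":
            r = rng.choice(other_rows, 590, replace=False)
            add(c, r, np.full(590, 5))  # 2,950 non-mito UMIs
            add(c, mito_rows, np.full(n_mito, 159))  # 1,590 / 4,540 = 35%
        elif kind == "hemo":
            r = rng.choice(other_rows, 597, replace=False)
            add(c, r, np.full(597, 8))  # 4,776 non-hemo UMIs
            add(c, hemo_rows, np.full(3, 177))  # 531 / 5,307 = 10%
        else:  # pass: 600 genes, ~5,000 UMIs, mito 2%, hemo 0
            r = rng.choice(other_rows, 595, replace=False)
            add(c, r, rng.integers(5, 12, size=595))
            add(c, mito_rows[:5], np.full(5, 10))
    counts = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(genes), n_cells)
    ).tocsr()
    cell_ids = np.asarray([f"QC{i + 1:03d}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {
            "sample_id": "QC_s1",
            "group": "DS",
            "tissue": "skin",
            "cell_type": "Fibro",
        },
        index=cell_ids,
    )
    expr = LabeledExpression(counts=counts, gene_ids=genes, cell_ids=cell_ids, meta=meta)
    return expr, n_cells - 17
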