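"""Run configuration: the thresholds driving every pipeline stage.

Defaults reproduce the published analysis settings: composition
|log2FC| > 0.1, differential expression |log2FC| > 0.25 at BH-adjusted
p < 0.01, ligand/receptor log2FC magnitude 0.2, GSEA significance at
adjusted p < 0.05 with |NES| >= 1, and an AUC > 0.7 biomarker call.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import yaml

from .data import ConfigError
from .qc import QCThresholds


@dataclass
class StemConfig:
    """Short time-series profile-clustering settings."""

    c: int = 2              # max unit change per step
    m: int = 50             # max model profiles retained
    n_perm: int = 1000      # cap on column-order permutations
    alpha: float = 0.05     # Bonferroni-adjusted significance level

    def __post_init__(self) -> None:
        if self.c < 1 or self.m < 1 or self.n_perm < 1:
            raise ConfigError("STEM c, m and n_perm must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("STEM alpha must lie in (0, 1)")


@dataclass
class GseaConfig:
    nperm: int = 1000
    adjp: float = 0.05
    nes_min: float = 1.0
    weight_p: float = 1.0

    def __post_init__(self) -> None:
        if self.nperm < 1 or self.nes_min <= 0:
            raise ConfigError("GSEA nperm and nes_min must be positive")
        if not 0 < self.adjp < 1:
            raise ConfigError("GSEA adjp must lie in (0, 1)")


@dataclass
class RunConfig:
    """All tunable thresholds for a pipeline run, plus the master seed."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    prop_log2fc_thr: float = 0.1
    de_logfc_thr: float = 0.25
    de_adjp_thr: float = 0.01
    lr_logfc_thr: float = 0.2
    stem: StemConfig = field(default_factory=StemConfig)
    gsea: GseaConfig = field(default_factory=GseaConfig)
    auc_thr: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_log2fc_thr", "de_logfc_thr", "lr_logfc_thr", "auc_thr"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not 0 < self.de_adjp_thr < 1:
            raise ConfigError("de_adjp_thr must lie in (0, 1)")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "qc" in kwargs:
            kwargs["qc"] = QCThresholds(**kwargs["qc"])
        if "stem" in kwargs:
            kwargs["stem"] = StemConfig(**kwargs["stem"])
        if "gsea" in kwargs:
            kwargs["gsea"] = GseaConfig(**kwargs["gsea"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed.

    Mixing a CRC32 of the stage name keeps partial re-runs reproducible:
    re-running one stage with the same master seed replays the exact
    random stream it saw inside a full run.  Result is always < 2**31.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)
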