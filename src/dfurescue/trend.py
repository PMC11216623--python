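"""Short time-series profile clustering in the STEM style.

Model profiles are piecewise-linear templates of integer unit changes
per step, each in [-c, c].  All (2c+1)^(T-1) candidates are enumerated;
when more than ``m`` exist, a greedy max-min-distance selection keeps
``m`` representatives (always retaining the flat profile).  Genes are
assigned to the profile with the highest Pearson correlation after
translation to start at zero, and per-profile enrichment is assessed
against a column-permutation null with a binomial tail and Bonferroni
correction.

A profile whose value vector rises to a strictly interior maximum and
then falls is a "rescue down" trend (up-then-down); the mirror image is
"rescue up".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ConfigError, ValidationError
from .differential import DEGSets


@dataclass(frozen=True)
class ModelProfile:
    id: int
    steps: tuple[int, ...]

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.steps, dtype=float)])

    @property
    def is_flat(self) -> bool:
        return all(s == 0 for s in self.steps)


@dataclass
class ProfileAssignment:
    """Gene memberships plus per-profile enrichment statistics."""

    genes: pd.DataFrame      # index gene: profile_id, r
    profiles: pd.DataFrame   # index profile_id: steps, trend_class, observed,
                             # expected_frac, p, p_adj, significant

    def rescue_genes(self, direction: str, significant_only: bool = True) -> set:
        """Genes assigned to (significant) profiles of one rescue class."""
        prof = self.profiles
        sel = prof["trend_class"] == f"rescue_{direction}"
        if significant_only and "significant" in prof.columns:
            sel &= prof["significant"].fillna(False)
        ids = set(prof.index[sel])
        return set(self.genes.index[self.genes["profile_id"].isin(ids)])


def make_profiles(T: int, c: int, m: int) -> list[ModelProfile]:
    """Enumerate and, if needed, down-select the model profiles.

    Candidates are ordered lexicographically by step vector (ids follow
    enumeration order).  Selection greedily maximizes the minimum pairwise
    distance 1 - Pearson r between value vectors, seeded with the flat
    profile; ties go to the lowest id, so the result is deterministic.
    """
    if T < 2 or c < 1 or m < 1:
        raise ConfigError("need T >= 2, c >= 1, m >= 1")
    candidates = [
        ModelProfile(id=i, steps=steps)
        for i, steps in enumerate(itertools.product(range(-c, c + 1), repeat=T - 1))
    ]
    if len(candidates) <= m:
        return candidates

    values = np.asarray([p.values for p in candidates])
    z = _row_standardize(values)  # zero rows stay zero (flat profile)
    flat_idx = next(i for i, p in enumerate(candidates) if p.is_flat)

    selected = [flat_idx]
    # distance to the flat profile: undefined correlation -> distance 1
    min_dist = np.ones(len(candidates))
    min_dist[flat_idx] = 0.0
    while len(selected) < m:
        best = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        selected.append(best)
        r = z @ z[best]
        dist = 1.0 - r
        nonflat = ~np.isclose(np.linalg.norm(z, axis=1), 0.0)
        dist = np.where(nonflat, dist, 1.0)
        dist[best] = 0.0
        min_dist = np.minimum(min_dist, dist)
    return [candidates[i] for i in sorted(selected)]


def assign_genes(series: pd.DataFrame, profiles: list[ModelProfile]) -> ProfileAssignment:
    """Assign each gene series to its best-correlated model profile.

    Series are translated to start at zero before correlation (Pearson r
    is additionally invariant to constant shifts and positive scaling).
    Constant series go to the flat profile; exact ties go to the lowest
    profile id.
    """
    T = series.shape[1]
    if any(len(p.steps) != T - 1 for p in profiles):
        raise ValidationError("profiles and series disagree on the number of timepoints")
    X = series.to_numpy(dtype=float)
    X = X - X[:, [0]]
    P = np.asarray([p.values for p in profiles])
    Xz = _row_standardize(X)
    Pz = _row_standardize(P)
    r = Xz @ Pz.T

    flat_pos = next((i for i, p in enumerate(profiles) if p.is_flat), None)
    const_gene = np.isclose(np.linalg.norm(Xz, axis=1), 0.0)
    const_prof = np.isclose(np.linalg.norm(Pz, axis=1), 0.0)
    r[:, const_prof] = -2.0          # undefined correlation: never best...
    if flat_pos is not None:
        r[const_gene, :] = -2.0
        r[const_gene, flat_pos] = 2.0  # ...except constant genes -> flat
    best = np.argmax(r, axis=1)
    best_r = r[np.arange(len(X)), best]
    best_r = np.clip(best_r, -1.0, 1.0)  # sentinel values back to range

    genes = pd.DataFrame(
        {"profile_id": [profiles[b].id for b in best], "r": best_r},
        index=list(series.index),
    )
    observed = genes["profile_id"].value_counts()
    prof_table = pd.DataFrame(
        {
            "steps": [p.steps for p in profiles],
            "trend_class": [classify_trend(p) for p in profiles],
            "observed": [int(observed.get(p.id, 0)) for p in profiles],
        },
        index=pd.Index([p.id for p in profiles], name="profile_id"),
    )
    return ProfileAssignment(genes=genes, profiles=prof_table)


def profile_significance(
    assignment: ProfileAssignment,
    series: pd.DataFrame,
    profiles: list[ModelProfile],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ProfileAssignment:
    """Permutation enrichment of each profile's observed gene count.

    The null reassigns genes after permuting the timepoint order; the
    expected fraction per profile is the mean assignment frequency over
    permutations, and p is the binomial upper tail
    P(X >= observed | n_genes, expected).  Bonferroni over profiles.
    """
    T = series.shape[1]
    n_genes = len(series)
    all_perms = list(itertools.permutations(range(T)))
    if len(all_perms) <= n_perm:
        perms = all_perms
    else:
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(T)) for _ in range(n_perm)]

    ids = list(assignment.profiles.index)
    freq = pd.Series(0.0, index=ids)
    X = series.to_numpy(dtype=float)
    for perm in perms:
        permuted = pd.DataFrame(X[:, list(perm)], index=series.index)
        counts = assign_genes(permuted, profiles).genes["profile_id"].value_counts()
        freq = freq.add(counts.reindex(ids, fill_value=0) / n_genes, fill_value=0.0)
    expected_frac = freq / len(perms)

    prof = assignment.profiles.copy()
    prof["expected_frac"] = expected_frac
    prof["p"] = [
        float(stats.binom.sf(obs - 1, n_genes, ef)) if ef > 0 else (1.0 if obs == 0 else 0.0)
        for obs, ef in zip(prof["observed"], prof["expected_frac"])
    ]
    m = len(prof)
    prof["p_adj"] = np.minimum(1.0, prof["p"] * m)
    prof["significant"] = prof["p_adj"] < alpha
    return ProfileAssignment(genes=assignment.genes.copy(), profiles=prof)


def classify_trend(profile: ModelProfile | np.ndarray) -> str:
    """Rescue class of a profile's value vector.

    rescue_down: the global maximum is strictly interior, the net change
    before it is positive and after it negative (up-then-down);
    rescue_up is symmetric around the minimum.  Extrema attained at an
    endpoint never qualify.
    """
    values = profile.values if isinstance(profile, ModelProfile) else np.asarray(profile, float)
    T = len(values)
    if T < 3:
        return "other"
    vmax, vmin = values.max(), values.min()
    # endpoint attainment disqualifies even if an interior point ties it
    down = False
    if not (values[0] == vmax or values[-1] == vmax):
        i = int(np.argmax(values))
        down = values[i] - values[0] > 0 and values[-1] - values[i] < 0
    up = False
    if not (values[0] == vmin or values[-1] == vmin):
        i = int(np.argmin(values))
        up = values[i] - values[0] < 0 and values[-1] - values[i] > 0
    if down and up:  # zigzag: the dominant excursion decides; a tie is neither
        rise, dip = vmax - values[0], values[0] - vmin
        if rise == dip:
            return "other"
        return "rescue_down" if rise > dip else "rescue_up"
    if down:
        return "rescue_down"
    if up:
        return "rescue_up"
    return "other"


@dataclass
class RescueIntersection:
    common_up: set = field(default_factory=set)
    common_down: set = field(default_factory=set)
    unique_up: set = field(default_factory=set)
    unique_down: set = field(default_factory=set)


def intersect_rescue(
    sc_sets: DEGSets,
    bulk: ProfileAssignment,
    acute: ProfileAssignment | None,
) -> RescueIntersection:
    """Cross-dataset rescue-gene logic.

    "Common" genes reverse in both the single-cell contrasts and the bulk
    trend series (direction-matched); "unique" genes additionally do not
    reverse the same way during acute wound healing, isolating changes
    specific to the diabetic process.  Symbols are uppercased first.
    """
    out = RescueIntersection()
    for direction in ("up", "down"):
        sc = {g.upper() for g in sc_sets.gene_level(f"rescue_{direction}")}
        bk = {g.upper() for g in bulk.rescue_genes(direction)}
        ac = (
            {g.upper() for g in acute.rescue_genes(direction)} if acute is not None else set()
        )
        common = sc & bk
        setattr(out, f"common_{direction}", common)
        setattr(out, f"unique_{direction}", common - ac)
    return out


def _row_standardize(x: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; all-constant rows become zero."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, x / norms, 0.0)
    return z
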