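import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dfurescue as dr
from dfurescue.differential import log2_fold_change


def exact_two_sided_p(a, b):
    """Oracle: enumerate every rank assignment of the combined sample."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    counts = {}
    for comb in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in comb]
        rest = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = sum(1 for x in grp for y in rest if x > y)
        counts[u] = counts.get(u, 0) + 1
    total = sum(counts.values())
    lo = sum(c for u, c in counts.items() if u <= u_obs)
    hi = sum(c for u, c in counts.items() if u >= u_obs)
    return min(1.0, 2 * min(lo, hi) / total)


class TestEligibility:
    def test_three_cells_in_both_groups_is_eligible(self, make_expr):
        expr = make_expr(
            np.ones((2, 6), int),
            groups=["DS"] * 3 + ["DFUNH"] * 3,
            cell_types=["A"] * 6,
        )
        assert dr.eligible_cell_types(expr, "DFUNH", "DS") == ["A"]

    def test_two_cells_is_not_enough(self, make_expr):
        expr = make_expr(
            np.ones((2, 5), int),
            groups=["DS"] * 3 + ["DFUNH"] * 2,
            cell_types=["A"] * 5,
        )
        assert dr.eligible_cell_types(expr, "DFUNH", "DS") == []

    def test_type_absent_from_one_group_is_excluded(self, make_expr):
        """Mirrors blood platelets missing from a clinical group."""
        expr = make_expr(
            np.ones((2, 9), int),
            groups=["DS"] * 6 + ["DFUNH"] * 3,
            cell_types=["Platelet"] * 3 + ["NK"] * 3 + ["NK"] * 3,
            tissue="blood",
        )
        assert dr.eligible_cell_types(expr, "DFUNH", "DS") == ["NK"]


class TestRankSumP:
    def test_exact_worked_example(self):
        assert dr.rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert exact_two_sided_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_distributions(self):
        assert dr.rank_sum_p([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 4, 6, 9], [2, 3, 7, 8]),
            ([10, 11, 12], [1, 2, 20, 21]),
            ([1, 2, 3, 4, 5], [6, 7, 8]),
        ],
    )
    def test_exact_path_matches_enumeration_oracle(self, a, b):
        assert dr.rank_sum_p(a, b) == pytest.approx(exact_two_sided_p(a, b), abs=1e-12)

    def test_asymptotic_tracks_enumeration_at_n8(self):
        """Every achievable U at n1 = n2 = 8 agrees within 0.01."""
        x = np.arange(1.0, 17.0)
        worst = 0.0
        seen = set()
        for comb in itertools.combinations(range(16), 8):
            a, b = x[list(comb)], np.delete(x, list(comb))
            u = int(sum(1 for v in a for w in b if v > w))
            if u in seen:
                continue
            seen.add(u)
            pe = exact_two_sided_p(a, b)
            pa = dr.rank_sum_p_asymptotic(a, b)[0]
            worst = max(worst, abs(pe - pa))
        assert worst < 0.01


class TestWilcoxonDE:
    def test_swap_symmetry(self, cohort):
        ab = dr.wilcoxon_de(cohort["expr"], "Fibro", "DFUNH", "DS")
        ba = dr.wilcoxon_de(cohort["expr"], "Fibro", "DS", "DFUNH")
        assert np.allclose(ab["p"], ba["p"])
        assert np.allclose(ab["log2fc"], -ba["log2fc"])

    def test_log2fc_back_transformed_hand_value(self):
        a = np.full((1, 5), math.log(2.0))
        b = np.zeros((1, 5))
        assert log2_fold_change(a, b)[0] == pytest.approx(1.0)

    def test_all_zero_gene_gets_p_one(self, make_expr):
        counts = np.array([[0, 0, 0, 0, 0, 0], [1, 2, 3, 1, 2, 3]])
        expr = dr.normalize(
            make_expr(counts, groups=["DS"] * 3 + ["DFUNH"] * 3)
        )
        de = dr.wilcoxon_de(expr, "Fibro", "DFUNH", "DS")
        assert de.loc["g1", "p"] == 1.0
        assert de.loc["g1", "log2fc"] == 0.0

    def test_missing_cell_type_raises(self, cohort):
        with pytest.raises(dr.ValidationError):
            dr.wilcoxon_de(cohort["expr"], "NoSuchType", "DFUNH", "DS")


class TestBHAdjust:
    def brute_force(self, p):
        """Step-up definition applied literally."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_hand_example(self):
        assert np.allclose(dr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert dr.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 60))
            assert np.max(np.abs(dr.bh_adjust(p) - self.brute_force(p))) < 1e-12

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_property(self, p):
        assert np.allclose(dr.bh_adjust(p), self.brute_force(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(dr.ValidationError):
            dr.bh_adjust([0.5, 1.5])


class TestDEGSets:
    @staticmethod
    def de_frame(entries):
        """entries: gene -> (log2fc, p_adj)"""
        return pd.DataFrame(
            {
                "log2fc": [v[0] for v in entries.values()],
                "p": [v[1] for v in entries.values()],
                "p_adj": [v[1] for v in entries.values()],
                "n_a": 10,
                "n_b": 10,
            },
            index=list(entries),
        )

    def test_rescue_up_requires_both_contrasts(self):
        un = {"A": self.de_frame({"g1": (-0.3, 0.001), "g2": (-0.3, 0.001)})}
        he = {"A": self.de_frame({"g1": (0.4, 0.005), "g2": (0.1, 0.5)})}
        sets = dr.call_deg_sets(un, he)
        assert sets.per_cell_type["A"]["rescue_up"] == {"g1"}
        assert sets.per_cell_type["A"]["rescue_down"] == frozenset()

    def test_rescue_sets_nested_in_contrast_sets(self, cohort_de):
        sets = dr.call_deg_sets(cohort_de["unhealing"], cohort_de["healing"])
        for ct, named in sets.per_cell_type.items():
            assert named["rescue_up"] <= named["unhealing_down"] & named["healing_up"]
            assert named["rescue_down"] <= named["unhealing_up"] & named["healing_down"]

    def test_mismatched_universes_rejected(self):
        un = {"A": self.de_frame({"g1": (-0.3, 0.001)})}
        he = {"B": self.de_frame({"g1": (0.4, 0.005)})}
        with pytest.raises(dr.ValidationError):
            dr.call_deg_sets(un, he)

    def test_gene_level_union_and_cross_tissue_intersection(self):
        un = {
            "A": self.de_frame({"g1": (-0.5, 0.001), "g2": (0.5, 0.001)}),
            "B": self.de_frame({"g1": (-0.5, 0.001), "g2": (0.0, 0.9)}),
        }
        he = {
            "A": self.de_frame({"g1": (0.5, 0.001), "g2": (-0.5, 0.001)}),
            "B": self.de_frame({"g1": (0.5, 0.001), "g2": (0.0, 0.9)}),
        }
        skin = dr.call_deg_sets(un, he)
        assert skin.gene_level("rescue_up") == {"g1"}
        blood = dr.call_deg_sets(
            {"C": self.de_frame({"g1": (-0.5, 0.001), "g3": (-0.5, 0.001)})},
            {"C": self.de_frame({"g1": (0.5, 0.001), "g3": (0.5, 0.001)})},
        )
        shared = dr.shared_across_tissues(skin, blood)
        assert shared["rescue_up"] == {"g1"}


class TestPlantedRecovery:
    def test_rescue_deg_sensitivity_and_precision(self, cohort, cohort_de):
        """Planted 2-fold reversal genes are recovered nearly perfectly."""
        manifest = cohort["manifest"]
        sets = dr.call_deg_sets(cohort_de["unhealing"], cohort_de["healing"])
        up, down = sets.rescue_pairs("up"), sets.rescue_pairs("down")
        planted_up = {
            (r.gene, r.cell_type) for r in manifest.rescue_genes if r.direction == "up"
        }
        planted_down = {
            (r.gene, r.cell_type) for r in manifest.rescue_genes if r.direction == "down"
        }
        truth_up, truth_down = set(planted_up), set(planted_down)
        for rev in manifest.lr_reversals:  # LR genes are planted reversals too
            lig, rec = rev.pair_name.split("-")
            tgt = truth_up if rev.direction == "up" else truth_down
            tgt.add((lig, rev.sender))
            for sub in rec.split("_"):
                tgt.add((sub, rev.receiver))
        tp = len(up & planted_up) + len(down & planted_down)
        assert tp / 20 >= 0.8
        detected = len(up) + len(down)
        true_hits = len(up & truth_up) + len(down & truth_down)
        assert detected > 0 and true_hits / detected >= 0.8
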