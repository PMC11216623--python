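import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dfurescue as dr
from dfurescue.simulate import PlantedTrendGene, simulate_trend_series
from dfurescue.trend import ModelProfile, RescueIntersection, classify_trend


class TestMakeProfiles:
    @pytest.mark.parametrize("T,c,expected", [(3, 1, 9), (4, 2, 125), (4, 1, 27), (5, 1, 81)])
    def test_full_enumeration_count(self, T, c, expected):
        assert len(dr.make_profiles(T, c, expected)) == expected

    def test_selection_keeps_flat_and_size(self):
        sel = dr.make_profiles(4, 2, 50)
        assert len(sel) == 50
        assert any(p.is_flat for p in sel)

    def test_selection_is_deterministic(self):
        a = dr.make_profiles(4, 2, 30)
        b = dr.make_profiles(4, 2, 30)
        assert [p.steps for p in a] == [p.steps for p in b]

    def test_values_are_cumulative_steps(self):
        p = ModelProfile(id=0, steps=(1, -2, 1))
        assert list(p.values) == [0.0, 1.0, -1.0, 0.0]


class TestAssignGenes:
    def test_hand_example_correlation(self):
        profiles = dr.make_profiles(3, 1, 9)
        series = pd.DataFrame([[1.0, 0.2, 1.1]], index=["g"], columns=list("abc"))
        asg = dr.assign_genes(series, profiles)
        best = profiles[asg.genes.loc["g", "profile_id"]]
        assert best.steps == (-1, 1)
        assert asg.genes.loc["g", "r"] == pytest.approx(0.995, abs=0.001)

    def test_constant_series_goes_to_flat(self):
        profiles = dr.make_profiles(3, 1, 9)
        series = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=list("abc"))
        asg = dr.assign_genes(series, profiles)
        assert profiles[asg.genes.loc["g", "profile_id"]].is_flat

    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_invariant_to_shift_and_positive_scale(self, shift, scale):
        profiles = dr.make_profiles(3, 1, 9)
        base = pd.DataFrame([[1.0, 0.2, 1.1]], index=["g"], columns=list("abc"))
        moved = base * scale + shift
        a = dr.assign_genes(base, profiles).genes.loc["g", "profile_id"]
        b = dr.assign_genes(moved, profiles).genes.loc["g", "profile_id"]
        assert a == b

    def test_planted_profiles_recovered_at_sigma_01(self):
        planted = [PlantedTrendGene(f"P{i:03d}", (-1, 1)) for i in range(200)]
        series = simulate_trend_series(
            planted, 0, ["DS", "DFUNH", "DFUH"], sigma=0.1, seed=1
        )
        profiles = dr.make_profiles(3, 1, 9)
        target = next(p.id for p in profiles if p.steps == (-1, 1))
        asg = dr.assign_genes(series, profiles)
        assert (asg.genes["profile_id"] == target).mean() >= 0.95


class TestProfileSignificance:
    def test_concentrated_assignment_is_significant(self):
        planted = [PlantedTrendGene(f"P{i:03d}", (-1, 1)) for i in range(100)]
        series = simulate_trend_series(
            planted, 0, list("abc"), sigma=0.05, seed=0
        )
        profiles = dr.make_profiles(3, 1, 9)
        asg = dr.profile_significance(
            dr.assign_genes(series, profiles), series, profiles, n_perm=1000, seed=0
        )
        target = next(p.id for p in profiles if p.steps == (-1, 1))
        assert asg.profiles.loc[target, "p"] < 1e-6
        assert asg.profiles.loc[target, "significant"]

    def test_expected_equals_observed_is_not_significant(self):
        """A profile observed exactly at its null expectation has a large p."""
        from scipy import stats

        p = float(stats.binom.sf(99, 900, 100 / 900))
        assert p > 0.4

    def test_null_series_controls_significant_profiles(self):
        profiles = dr.make_profiles(3, 1, 9)
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            series = pd.DataFrame(
                rng.normal(5, 1, size=(200, 3)),
                index=[f"g{i}" for i in range(200)],
                columns=list("abc"),
            )
            asg = dr.profile_significance(
                dr.assign_genes(series, profiles), series, profiles, seed=seed
            )
            total += int(asg.profiles["significant"].sum())
        assert total <= 4  # Bonferroni-level control over 10 x 9 profile tests

    def test_bonferroni_relation(self):
        planted = [PlantedTrendGene("P1", (1, -1))]
        series = simulate_trend_series(planted, 50, list("abc"), sigma=0.2, seed=3)
        profiles = dr.make_profiles(3, 1, 9)
        asg = dr.profile_significance(
            dr.assign_genes(series, profiles), series, profiles, seed=3
        )
        expect = np.minimum(1.0, asg.profiles["p"] * len(profiles))
        assert np.allclose(asg.profiles["p_adj"], expect)


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "steps,expected",
        [
            ((1, -1), "rescue_down"),
            ((-1, 1), "rescue_up"),
            ((1, 1, -2), "rescue_down"),
            ((0, 0), "other"),
            ((1, 1), "other"),
            ((-2, 1), "rescue_up"),       # ends below start: still an interior dip
            ((1, 0, -1), "rescue_down"),  # plateau at the top, interior max
            ((1, -1, 1), "other"),        # endpoint ties the interior max
        ],
    )
    def test_step_patterns(self, steps, expected):
        assert classify_trend(ModelProfile(id=0, steps=steps)) == expected

    @given(st.lists(st.integers(-2, 2), min_size=2, max_size=6))
    def test_negating_values_swaps_rescue_classes(self, steps):
        fwd = classify_trend(ModelProfile(id=0, steps=tuple(steps)))
        neg = classify_trend(ModelProfile(id=0, steps=tuple(-s for s in steps)))
        swap = {"rescue_up": "rescue_down", "rescue_down": "rescue_up", "other": "other"}
        assert neg == swap[fwd]


class TestIntersectRescue:
    @staticmethod
    def sc_sets(up=(), down=()):
        sets = dr.DEGSets()
        sets.per_cell_type["X"] = {
            "unhealing_up": frozenset(down),
            "unhealing_down": frozenset(up),
            "healing_up": frozenset(up),
            "healing_down": frozenset(down),
            "rescue_up": frozenset(up),
            "rescue_down": frozenset(down),
        }
        return sets

    @staticmethod
    def assignment(up=(), down=()):
        genes = pd.DataFrame(
            {"profile_id": [1] * len(up) + [2] * len(down), "r": 1.0},
            index=list(up) + list(down),
        )
        profiles = pd.DataFrame(
            {
                "steps": [(-1, 1), (1, -1)],
                "trend_class": ["rescue_up", "rescue_down"],
                "observed": [len(up), len(down)],
                "significant": [True, True],
            },
            index=pd.Index([1, 2], name="profile_id"),
        )
        return dr.ProfileAssignment(genes=genes, profiles=profiles)

    def test_set_algebra_example(self):
        sc = self.sc_sets(up=("A", "B", "C"))
        bulk = self.assignment(up=("B", "C", "D"))
        acute = self.assignment(up=("C",))
        res = dr.intersect_rescue(sc, bulk, acute)
        assert res.common_up == {"B", "C"}
        assert res.unique_up == {"B"}

    def test_empty_acute_means_unique_equals_common(self):
        sc = self.sc_sets(up=("A", "B"))
        bulk = self.assignment(up=("A", "B"))
        res = dr.intersect_rescue(sc, bulk, None)
        assert res.unique_up == res.common_up == {"A", "B"}

    def test_symbols_harmonized_by_case(self):
        sc = self.sc_sets(down=("mmp2",))
        bulk = self.assignment(down=("MMP2",))
        res = dr.intersect_rescue(sc, bulk, None)
        assert res.common_down == {"MMP2"}

    def test_recovery_with_overlapping_planted_sets(self):
        """Genes reversed in sc+bulk but also in acute are excluded; F1 >= 0.9."""
        rng = np.random.default_rng(5)
        genes = [f"G{i:03d}" for i in range(60)]
        sc_up = set(genes[:30])
        bulk_up_genes = genes[:24] + genes[40:46]  # 24 overlap + 6 bulk-only
        acute_up_genes = genes[:8] + genes[50:55]  # 8 of the overlap also acute
        planted_unique = set(genes[8:24])

        bulk_series = simulate_trend_series(
            [PlantedTrendGene(g, (-1, 1)) for g in bulk_up_genes],
            40, ["DS", "DFUNH", "DFUH"], sigma=0.1, seed=int(rng.integers(1e6)),
        )
        acute_series = simulate_trend_series(
            [PlantedTrendGene(g, (-1, -1, 1)) for g in acute_up_genes],
            40, ["d0", "d1", "d3", "d7"], sigma=0.1, seed=int(rng.integers(1e6)),
        )
        p3 = dr.make_profiles(3, 1, 9)
        p4 = dr.make_profiles(4, 1, 27)
        bulk = dr.profile_significance(
            dr.assign_genes(bulk_series, p3), bulk_series, p3, seed=0
        )
        acute = dr.profile_significance(
            dr.assign_genes(acute_series, p4), acute_series, p4, seed=0
        )
        res = dr.intersect_rescue(self.sc_sets(up=tuple(sc_up)), bulk, acute)
        tp = len(res.unique_up & planted_unique)
        prec = tp / max(len(res.unique_up), 1)
        rec = tp / len(planted_unique)
        f1 = 2 * prec * rec / max(prec + rec, 1e-9)
        assert f1 >= 0.9
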