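"""HDR composite, PCA priority rank, indicator flags, veto semantics, categories."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mangrovesdm.prioritize import (
    CATEGORY_SPECIES,
    NEGATIVE_FLAGS,
    POSITIVE_FLAGS,
    IndicatorThresholds,
    assign_category,
    combine_flags,
    flag_grid,
    grid_category,
    human_disturbance_rate,
    species_priority_rank,
)
from mangrovesdm.species import UnknownSpeciesError


def comp_frame(built, pop, road, agri):
    return pd.DataFrame(
        {
            "built_pct": built,
            "population": pop,
            "road_density": road,
            "agriculture_pct": agri,
        }
    )


class TestHdr:
    def test_all_zero_gives_zero(self):
        df = comp_frame([0.0, 50.0], [0, 1000], [0, 2.0], [0.0, 40.0])
        assert human_disturbance_rate(df)[0] == 0.0

    def test_all_at_maximum_gives_hundred(self):
        df = comp_frame([100.0, 10.0], [500, 100], [3.0, 1.0], [100.0, 5.0]).iloc[[0]]
        assert human_disturbance_rate(df)[0] == pytest.approx(100.0)

    def test_halfway_components_give_fifty(self):
        df = comp_frame([50.0, 0.0], [500, 1000], [1.0, 2.0], [50.0, 0.0])
        assert human_disturbance_rate(df)[0] == pytest.approx(50.0)

    def test_monotone_in_each_component(self):
        rng = np.random.default_rng(0)
        base = comp_frame(
            rng.uniform(0, 100, 20), rng.integers(0, 5000, 20), rng.uniform(0, 4, 20), rng.uniform(0, 100, 20)
        )
        h0 = human_disturbance_rate(base)
        for col in base.columns:
            bumped = base.copy()
            # raise one component of one non-maximal grid
            j = int(base[col].idxmin())
            bumped.loc[j, col] = base[col].max()
            h1 = human_disturbance_rate(bumped)
            assert h1[j] >= h0[j] - 1e-9

    def test_negative_component_rejected(self):
        df = comp_frame([10.0], [-5], [0.5], [20.0])
        with pytest.raises(ValueError):
            human_disturbance_rate(df)


class TestPriorityRank:
    def attrs(self, rows, codes=None):
        codes = codes or [f"S{i}" for i in range(len(rows))]
        return pd.DataFrame(
            rows,
            columns=[
                "niche_breadth",
                "potential_distribution",
                "degradation_exposure",
                "conservation_status_score",
            ],
            index=codes,
        )

    def test_dominant_endangered_species_ranks_first(self):
        a = self.attrs(
            [[0.9, 0.9, 90.0, 3], [0.2, 0.3, 10.0, 1], [0.3, 0.2, 20.0, 1]],
            codes=["HF", "AC", "AA"],
        )
        ranks = species_priority_rank(a)
        assert ranks.loc["HF", "priority_rank"] == 1

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(1)
        a = self.attrs(rng.random((8, 4)).tolist())
        ranks = species_priority_rank(a)
        assert sorted(ranks["priority_rank"]) == list(range(1, 9))

    def test_identical_rows_tie_broken_by_code(self):
        a = self.attrs([[0.5, 0.5, 50.0, 2], [0.5, 0.5, 50.0, 2], [0.1, 0.1, 5.0, 1]], codes=["BB", "AA", "CC"])
        ranks = species_priority_rank(a)
        assert abs(ranks.loc["AA", "priority_rank"] - ranks.loc["BB", "priority_rank"]) == 1
        assert ranks.loc["AA", "priority_rank"] < ranks.loc["BB", "priority_rank"]

    def test_single_variance_axis_orders_by_it(self):
        """One dominant attribute: ranks follow that axis (eigen oracle)."""
        rng = np.random.default_rng(2)
        n = 10
        axis = np.linspace(0, 1, n)
        rows = np.column_stack(
            [axis, 0.01 * rng.random(n), 0.01 * rng.random(n), 1 + axis * 2]
        )
        a = self.attrs(rows.tolist())
        ranks = species_priority_rank(a)
        # highest axis value -> rank 1
        expected = np.argsort(-axis) + 1
        got = ranks["priority_rank"].to_numpy()
        order = np.argsort(got)
        np.testing.assert_array_equal(np.argsort(-axis), order)

    def test_constant_attribute_dropped_with_warning(self):
        a = self.attrs([[0.5, 0.1, 10.0, 2], [0.2, 0.9, 30.0, 2], [0.8, 0.4, 50.0, 2]])
        with pytest.warns(UserWarning, match="constant"):
            ranks = species_priority_rank(a)
        assert len(ranks) == 3

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(ValueError):
            species_priority_rank(self.attrs([[0.5, 0.5, 5.0, 1]]))


class TestFlags:
    def base_inputs(self):
        return dict(
            cover_pct=10.0,
            hdr=10.0,
            suit_class=3,
            accretion_pct=0.0,
            degradation_pct=80.0,
            overlap_significant=False,
            rank_top_half=True,
        )

    def test_dense_mangrove_vetoed(self):
        flags = flag_grid(**{**self.base_inputs(), "cover_pct": 95.0})
        assert flags["n1"]
        assert not combine_flags(flags)

    def test_boundary_cover_eighty_not_vetoed(self):
        flags = flag_grid(**{**self.base_inputs(), "cover_pct": 80.0})
        assert not flags["n1"]

    def test_suitability_flags_mutually_exclusive(self):
        for cls in range(4):
            flags = flag_grid(**{**self.base_inputs(), "suit_class": cls})
            assert flags["p3"] == (cls >= 2)
            assert flags["n3"] == (cls <= 1)
            assert flags["p3"] != flags["n3"]

    def test_missing_input_named(self):
        with pytest.raises(ValueError, match="hdr"):
            flag_grid(**{**self.base_inputs(), "hdr": float("nan")})

    def test_strict_threshold_boundaries(self):
        t = IndicatorThresholds()
        flags = flag_grid(
            cover_pct=80.0,
            hdr=75.0,
            suit_class=2,
            accretion_pct=75.0,
            degradation_pct=75.0,
            overlap_significant=False,
            rank_top_half=False,
            thresholds=t,
        )
        assert not any(flags[n] for n in NEGATIVE_FLAGS)
        assert not flags["p4"]  # 75 is not > 75


class TestCombinationRule:
    def test_veto_overrides_everything(self):
        """Any negative flag removes the pair regardless of positives (2^8 sweep)."""
        for bits in itertools.product([False, True], repeat=8):
            flags = dict(zip(NEGATIVE_FLAGS + POSITIVE_FLAGS, bits))
            if any(flags[n] for n in NEGATIVE_FLAGS):
                assert not combine_flags(flags, rule="default")
                assert not combine_flags(flags, rule="count")
                assert not combine_flags(flags, rule="veto-only")

    def test_default_rule_truth_table(self):
        for bits in itertools.product([False, True], repeat=8):
            flags = dict(zip(NEGATIVE_FLAGS + POSITIVE_FLAGS, bits))
            expected = (
                not any(flags[n] for n in NEGATIVE_FLAGS)
                and flags["p3"]
                and (flags["p1"] or flags["p2"] or flags["p4"])
            )
            assert combine_flags(flags, rule="default") == expected

    def test_suitability_alone_insufficient(self):
        flags = dict.fromkeys(NEGATIVE_FLAGS + POSITIVE_FLAGS, False)
        flags["p3"] = True
        assert not combine_flags(flags)

    def test_degradation_threshold_monotonicity(self):
        """Raising the degradation cut never increases the prioritized count."""
        rng = np.random.default_rng(3)
        grids = [
            dict(
                cover_pct=rng.uniform(0, 100),
                hdr=rng.uniform(0, 100),
                suit_class=int(rng.integers(0, 4)),
                accretion_pct=rng.uniform(0, 100),
                degradation_pct=rng.uniform(0, 100),
                overlap_significant=bool(rng.integers(0, 2)),
                rank_top_half=bool(rng.integers(0, 2)),
            )
            for _ in range(300)
        ]
        prev = None
        for cut in (0.0, 25.0, 50.0, 75.0, 100.0):
            t = IndicatorThresholds(degradation_min=cut)
            count = sum(combine_flags(flag_grid(**g, thresholds=t)) for g in grids)
            if prev is not None:
                assert count <= prev
            prev = count


class TestCategories:
    @pytest.mark.parametrize("code,cat", [("HF", 4), ("NF", 5), ("AR", 1), ("AA", 2), ("BG", 3), ("SA", 6)])
    def test_species_category(self, code, cat):
        assert assign_category(code) == cat

    def test_unknown_code_rejected(self):
        with pytest.raises(UnknownSpeciesError):
            assign_category("ZZ")

    def test_full_set_beats_singletons(self):
        # all of category 2 prioritized -> 2, even though AA alone is also in 8
        assert grid_category({"AA", "AM", "AO"}) == 2
        assert grid_category({"AA"}) == 2  # falls back to lowest single-species category

    def test_category_one_complete_pair(self):
        assert grid_category({"AR", "AC"}) == 1
        assert grid_category({"AR"}) == 1

    def test_mixed_community_category_seven(self):
        assert grid_category(set(CATEGORY_SPECIES[7])) == 2  # cat 2 subset wins first

    def test_empty_or_uncategorized(self):
        assert grid_category(set()) is None
        assert grid_category({"LR"}) is None
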