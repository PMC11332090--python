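import numpy as np
import pandas as pd
import pytest

import phylofactory as pf
from phylofactory.biogeo import (
    alien_ratio_table,
    assign_region_mode,
    faith_pd,
    normalize_by_area,
    ses_pd,
)

import oracles
from conftest import random_binary_states, random_tree


def occ_table(rows):
    return pd.DataFrame(rows, columns=["species", "realm", "biome"])


class TestAssignRegionMode:
    def test_clear_mode_no_tie(self):
        occ = occ_table(
            [("sp1", "Palaearctic", "Desert")] * 3 + [("sp1", "Nearctic", "Desert")] * 2
        )
        out = assign_region_mode(occ)
        assert out.loc["sp1", "realm"] == "Palaearctic"
        assert not out.loc["sp1", "realm_tie"]
        assert out.loc["sp1", "n_records"] == 5

    def test_tie_broken_lexicographically_and_flagged(self):
        occ = occ_table(
            [("sp1", "Palaearctic", "Desert")] * 2 + [("sp1", "Nearctic", "Taiga")] * 2
        )
        out = assign_region_mode(occ)
        assert out.loc["sp1", "realm"] == "Nearctic"
        assert bool(out.loc["sp1", "realm_tie"])

    def test_levels_assigned_independently(self):
        occ = occ_table(
            [
                ("sp1", "Palaearctic", "Taiga"),
                ("sp1", "Palaearctic", "Desert"),
                ("sp1", "Nearctic", "Desert"),
            ]
        )
        out = assign_region_mode(occ)
        assert out.loc["sp1", "realm"] == "Palaearctic"
        assert out.loc["sp1", "biome"] == "Desert"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            assign_region_mode(occ_table([]))


class TestAlienRatioTable:
    @staticmethod
    def _fake_region(region, total, nat, inv, offset=0):
        species = [f"{region}_{i + offset:04d}" for i in range(total)]
        assignments = pd.DataFrame({"realm": region}, index=species)
        assignments.index.name = "species"
        status = pd.DataFrame(
            {
                "species": species,
                "naturalized": [1] * nat + [0] * (total - nat),
                "invasive": [1] * inv + [0] * (total - inv),
            }
        )
        return assignments, status

    def test_worked_percentages(self):
        # 150 species, 45 naturalized, 23 invasive -> 30.0% and 15.3%
        assignments, status = self._fake_region("Afrotropical", 150, 45, 23)
        table = alien_ratio_table(assignments, status, level="realm")
        row = table.loc["Afrotropical"]
        assert row["pct_naturalized"] == 30.0
        assert row["pct_invasive"] == 15.3

    def test_all_invasive_boundary(self):
        assignments, status = self._fake_region("X", 12, 12, 12)
        row = alien_ratio_table(assignments, status, level="realm").loc["X"]
        assert row["pct_naturalized"] == 100.0
        assert row["pct_invasive"] == 100.0

    def test_partition_property(self):
        a1, s1 = self._fake_region("R1", 40, 10, 5)
        a2, s2 = self._fake_region("R2", 25, 5, 2)
        assignments = pd.concat([a1, a2])
        status = pd.concat([s1, s2], ignore_index=True)
        table = alien_ratio_table(assignments, status, level="realm")
        assert table["total"].sum() == len(assignments)


class TestFaithPD:
    def test_hand_values(self, four_tip_tree):
        assert faith_pd(four_tip_tree, ["A"]) == pytest.approx(2.0)
        assert faith_pd(four_tip_tree, ["A", "B"]) == pytest.approx(3.0)
        assert faith_pd(four_tip_tree, list("ABCD")) == pytest.approx(6.0)

    def test_no_root_variant_drops_shared_path(self, four_tip_tree):
        assert faith_pd(four_tip_tree, ["A", "B"], include_root=False) == pytest.approx(2.0)
        assert faith_pd(four_tip_tree, ["A", "C"], include_root=False) == pytest.approx(4.0)

    def test_empty_or_unknown_rejected(self, four_tip_tree):
        with pytest.raises(ValueError):
            faith_pd(four_tip_tree, [])
        with pytest.raises(KeyError, match="Qq"):
            faith_pd(four_tip_tree, ["A", "Qq"])

    def test_monotone_under_union(self):
        tree = random_tree(25, seed=1)
        labels = tree.tip_labels
        base = labels[:6]
        pd0 = faith_pd(tree, base)
        for extra in labels[6:12]:
            assert faith_pd(tree, base + [extra]) >= pd0 - 1e-12

    @pytest.mark.parametrize("include_root", [True, False])
    def test_matches_edge_union_oracle(self, include_root):
        for seed in range(12):
            tree = random_tree(20, seed=2000 + seed)
            states = random_binary_states(tree.tip_labels, k=5, seed=seed)
            assemblage = [sp for sp, v in states.items() if v == 1]
            got = faith_pd(tree, assemblage, include_root=include_root)
            want = oracles.pd_edge_union(tree, assemblage, include_root=include_root)
            assert got == pytest.approx(want, abs=1e-12)


class TestSesPD:
    def test_reproducible_bit_identical(self):
        tree = random_tree(60, seed=3)
        assemblage = tree.tip_labels[:10]
        a = ses_pd(tree, assemblage, tree.tip_labels, n_null=50, seed=4)
        b = ses_pd(tree, assemblage, tree.tip_labels, n_null=50, seed=4)
        assert a == b

    def test_degenerate_pool_rejected(self):
        tree = random_tree(10, seed=3)
        with pytest.raises(ValueError, match="pool"):
            ses_pd(tree, tree.tip_labels, tree.tip_labels, n_null=10, seed=0)

    def test_single_species_assemblage_is_indeterminate(self):
        tree = random_tree(30, seed=6)
        r = ses_pd(tree, [tree.tip_labels[0]], tree.tip_labels, n_null=50, seed=1)
        assert np.isfinite(r.ses)
        assert r.verdict == "indeterminate"

    def test_null_draws_calibrate(self):
        tree = random_tree(150, seed=8)
        pool = tree.tip_labels
        rng = np.random.default_rng(9)
        ses_vals = []
        for rep in range(30):
            members = [pool[i] for i in rng.choice(150, size=15, replace=False)]
            ses_vals.append(ses_pd(tree, members, pool, n_null=100, seed=rep).ses)
        assert abs(np.mean(ses_vals)) < 0.5
        assert 0.6 < np.std(ses_vals) < 1.5

    def test_clade_assemblage_strongly_negative(self):
        tree = random_tree(200, seed=12)
        assign = pf.simulate_regional_assemblages(
            tree, n_regions=1, restriction=1.0, richness=20, seed=2
        )
        r = ses_pd(tree, list(assign.index), tree.tip_labels, n_null=100, seed=3)
        assert r.ses < -2
        assert r.verdict == "restrictive"


class TestNormalizeByArea:
    def test_simple_density(self):
        out = normalize_by_area({"X": 10.0}, {"X": 2.0}, per=1.0)
        assert out["X"] == pytest.approx(5.0)

    def test_zero_count_gives_zero(self):
        out = normalize_by_area({"X": 0.0}, {"X": 3.0})
        assert out["X"] == 0.0

    def test_row_order_irrelevant(self):
        counts = pd.Series({"A": 4.0, "B": 8.0})
        areas = pd.DataFrame({"region": ["B", "A"], "area_km2": [2.0, 4.0]})
        out = normalize_by_area(counts, areas, per=1.0)
        assert out["A"] == pytest.approx(1.0)
        assert out["B"] == pytest.approx(4.0)

    def test_missing_area_named(self):
        with pytest.raises(ValueError, match="X"):
            normalize_by_area({"X": 1.0}, {"Y": 2.0})
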