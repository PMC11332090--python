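import numpy as np
import pytest
from dendropy.calculate import treemeasure

import phylofactory as pf
from phylofactory.synthetic import (
    BIOMES,
    REALMS,
    generate_world,
    simulate_occurrences,
    simulate_regional_assemblages,
)

from conftest import random_tree


class TestBirthDeathTree:
    def test_smallest_case(self):
        t = pf.simulate_birth_death_tree(2, birth=1.0, death=0.0, seed=7)
        assert t.n_tips == 2

    def test_bifurcating_internal_count(self):
        t = pf.simulate_birth_death_tree(100, birth=1.0, death=0.0, seed=1)
        assert t.n_internal == 99

    def test_ultrametric(self):
        t = pf.simulate_birth_death_tree(50, birth=1.0, death=0.2, seed=2)
        depths = [t.root_path_length(x) for x in t.tip_labels]
        assert max(depths) - min(depths) < 1e-8

    def test_deterministic_and_seed_sensitive(self):
        a = pf.simulate_birth_death_tree(20, 1.0, 0.0, seed=5).to_newick()
        b = pf.simulate_birth_death_tree(20, 1.0, 0.0, seed=5).to_newick()
        c = pf.simulate_birth_death_tree(20, 1.0, 0.0, seed=6).to_newick()
        assert a == b
        assert a != c

    def test_unattainable_parameters_rejected(self):
        with pytest.raises(ValueError):
            pf.simulate_birth_death_tree(10, birth=1.0, death=1.0, seed=0)
        with pytest.raises(ValueError):
            pf.simulate_birth_death_tree(1, birth=1.0, death=0.0, seed=0)

    def test_pure_birth_gamma_centred_near_zero(self):
        """Under pure birth the gamma statistic is ~N(0,1)."""
        gammas = [
            treemeasure.pybus_harvey_gamma(
                pf.simulate_birth_death_tree(60, 1.0, 0.0, seed=s).dendropy_tree
            )
            for s in range(40)
        ]
        assert abs(np.mean(gammas)) < 0.5


class TestRandomTrait:
    def test_exact_prevalence_and_determinism(self):
        tree = random_tree(30, seed=3)
        a = pf.simulate_random_trait(tree, 7, seed=4)
        b = pf.simulate_random_trait(tree, 7, seed=4)
        c = pf.simulate_random_trait(tree, 7, seed=5)
        assert a.prevalence == 7
        assert a.states == b.states
        assert a.states != c.states

    @pytest.mark.parametrize("k", [0, 30])
    def test_boundary_prevalence_rejected(self, k):
        tree = random_tree(30, seed=3)
        with pytest.raises(ValueError):
            pf.simulate_random_trait(tree, k, seed=1)

    def test_uniform_marginal_inclusion(self):
        tree = random_tree(20, seed=8)
        freq = np.zeros(20)
        reps = 400
        for s in range(reps):
            tv = pf.simulate_random_trait(tree, 5, seed=s)
            freq += tv.aligned(tree)
        freq /= reps
        # each tip included w.p. 5/20 = 0.25; 4 sd binomial tolerance
        assert np.all(np.abs(freq - 0.25) < 4 * np.sqrt(0.25 * 0.75 / reps))


class TestThresholdBrownianTrait:
    def test_exact_prevalence(self):
        tree = random_tree(40, seed=2)
        tv = pf.simulate_threshold_brownian_trait(tree, 11, seed=0)
        assert tv.prevalence == 11

    def test_star_tree_indistinguishable_from_uniform(self):
        """On a star tree Brownian tip values are i.i.d., so the top-k
        set is a uniform random k-subset."""
        star = pf.parse_newick("(" + ",".join(f"t{i}:1" for i in range(12)) + ");")
        freq = np.zeros(12)
        reps = 600
        for s in range(reps):
            tv = pf.simulate_threshold_brownian_trait(star, 3, seed=s)
            freq += tv.aligned(star)
        freq /= reps
        assert np.all(np.abs(freq - 0.25) < 4 * np.sqrt(0.25 * 0.75 / reps))

    def test_two_clade_tree_concentrates_states(self):
        """With two deep clades the 1s coincide with one whole clade far
        more often than the hypergeometric baseline 1/C(8,4) ~ 1.4%."""
        clade1 = "((a1:0.1,a2:0.1):0.1,(a3:0.1,a4:0.1):0.1):10"
        clade2 = "((b1:0.1,b2:0.1):0.1,(b3:0.1,b4:0.1):0.1):10"
        tree = pf.parse_newick(f"({clade1},{clade2});")
        target = {"a1", "a2", "a3", "a4"}
        hits = 0
        reps = 200
        for s in range(reps):
            tv = pf.simulate_threshold_brownian_trait(tree, 4, seed=s)
            ones = {sp for sp, v in tv.states.items() if v == 1}
            hits += ones == target
        assert hits / reps > 0.30  # ~0.5 expected; baseline 0.014


class TestMkTrait:
    def test_zero_rate_inherits_root_state(self):
        tree = random_tree(25, seed=1)
        tv = pf.simulate_mk_trait(tree, rate=0.0, root_state=1, seed=0)
        assert all(v == 1 for v in tv.states.values())

    def test_high_rate_reaches_stationary_half(self):
        tree = random_tree(50, seed=4)
        fracs = [
            pf.simulate_mk_trait(tree, rate=50.0, root_state=0, seed=s).prevalence / 50
            for s in range(60)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_single_branch_change_probability_closed_form(self):
        """q*t = 0.5 gives P(change) = 1/2 - exp(-1)/2 ~ 0.3161."""
        tree = pf.parse_newick("(A:0.5,B:0.5);")
        reps = 1500
        changes = sum(
            pf.simulate_mk_trait(tree, rate=1.0, root_state=0, seed=s)["A"]
            for s in range(reps)
        )
        expected = 0.5 - 0.5 * np.exp(-1.0)
        assert changes / reps == pytest.approx(expected, abs=4 * np.sqrt(expected * (1 - expected) / reps))


class TestRegionalAssemblages:
    def test_sizes_disjoint_and_deterministic(self):
        tree = random_tree(60, seed=6)
        a = simulate_regional_assemblages(tree, 3, restriction=0.5, richness=[10, 15, 20], seed=1)
        b = simulate_regional_assemblages(tree, 3, restriction=0.5, richness=[10, 15, 20], seed=1)
        assert a.equals(b)
        assert a.value_counts().to_dict() == {"region3": 20, "region2": 15, "region1": 10}
        assert a.index.is_unique  # disjoint regions

    def test_richness_exceeding_pool_rejected(self):
        tree = random_tree(20, seed=6)
        with pytest.raises(ValueError):
            simulate_regional_assemblages(tree, 2, restriction=0.0, richness=[15, 10], seed=0)

    def test_full_restriction_yields_clade_members(self):
        tree = random_tree(100, seed=10)
        assign = simulate_regional_assemblages(tree, 1, restriction=1.0, richness=20, seed=3)
        members = set(assign.index)
        # members must sit inside a single small clade: the spanning
        # clade (MRCA subtree) should not be much bigger than the region
        mrca = tree.dendropy_tree.mrca(taxon_labels=sorted(members))
        spanning = {l.taxon.label for l in mrca.leaf_iter()}
        assert members <= spanning
        assert len(spanning) <= 40  # a uniform 20-sample spans ~the whole 100-tip tree


class TestOccurrences:
    def _truth(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        import pandas as pd

        return pd.DataFrame(
            {
                "realm": rng.choice(REALMS, size=n),
                "biome": rng.choice(BIOMES, size=n),
            },
            index=[f"sp{i:03d}" for i in range(n)],
        )

    def test_zero_noise_records_all_true(self):
        truth = self._truth()
        occ = simulate_occurrences(truth, n_records=5, noise=0.0, seed=1,
                                   realm_labels=REALMS, biome_labels=BIOMES)
        merged = occ.groupby("species")["realm"].nunique()
        assert (merged == 1).all()

    def test_mode_recovers_truth_under_noise(self):
        truth = self._truth(n=150, seed=2)
        occ = simulate_occurrences(truth, n_records=50, noise=0.3, seed=3,
                                   realm_labels=REALMS, biome_labels=BIOMES)
        assigned = pf.assign_region_mode(occ)
        recovery = (assigned["realm"] == truth.loc[assigned.index, "realm"]).mean()
        assert recovery >= 0.99

    def test_single_record_coin_flip_limit(self):
        truth = self._truth(n=400, seed=4)
        occ = simulate_occurrences(truth, n_records=1, noise=0.5, seed=5,
                                   realm_labels=REALMS, biome_labels=BIOMES)
        assigned = pf.assign_region_mode(occ)
        recovery = (assigned["realm"] == truth.loc[assigned.index, "realm"]).mean()
        assert recovery == pytest.approx(0.5, abs=0.1)


class TestWorld:
    def test_world_is_internally_consistent(self):
        w = generate_world(seed=11, n_tips=120)
        tips = set(w.tree.tip_labels)
        assert set(w.status["species"]) == tips
        assert set(w.regions.index) <= tips
        assert set(w.occurrences["species"]) <= tips
        # invasive is a subset of naturalized by construction
        st = w.status.set_index("species")
        assert not ((st["invasive"] == 1) & (st["naturalized"] == 0)).any()

    def test_world_reproducible_and_seed_sensitive(self):
        a = generate_world(seed=11, n_tips=80)
        b = generate_world(seed=11, n_tips=80)
        c = generate_world(seed=12, n_tips=80)
        assert a.status.equals(b.status)
        assert a.occurrences.equals(b.occurrences)
        assert not a.status.equals(c.status)
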