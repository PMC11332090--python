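"""Synthetic worlds: trees, clumped binary traits, regional assemblages.

Every generator is a pure function of (parameters, seed), so a whole
synthetic data set — phylogeny, naturalized/invasive status flags,
per-species source regions and noisy occurrence records — can be
regenerated bit-identically and fed through the same readers as real
data.

The trait generators span the two null hypotheses of the clumping
analysis: :func:`simulate_random_trait` scatters the state uniformly
over tips (no phylogenetic signal, the D = 1 pole) while
:func:`simulate_threshold_brownian_trait` thresholds a Brownian
character so close relatives share the state (the D = 0 pole).  The
Brownian machinery here is the single implementation also used for the
Brownian null inside the D estimator.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._arrays import TreeArrays
from .traits import TraitVector
from .treeio import Phylogeny

__all__ = [
    "REALMS",
    "BIOMES",
    "REALM_AREAS_KM2",
    "simulate_birth_death_tree",
    "simulate_random_trait",
    "simulate_threshold_brownian_trait",
    "simulate_nested_threshold_traits",
    "simulate_mk_trait",
    "simulate_regional_assemblages",
    "simulate_occurrences",
    "SyntheticWorld",
    "generate_world",
]

logger = logging.getLogger(__name__)

#: The six biogeographic realms used as the default realm label set.
REALMS = [
    "Afrotropical",
    "Australasian",
    "Indomalay",
    "Nearctic",
    "Neotropical",
    "Palaearctic",
]

#: Twelve terrestrial biomes used as the default biome label set.
BIOMES = [
    "Desert",
    "Mediterranean_shrub",
    "Montane_grassland",
    "Taiga",
    "Temp_broadleaf_forest",
    "Temp_coniferous_forest",
    "Temp_savanna_shrub",
    "Trop_coniferous_forest",
    "Trop_dry_forest",
    "Trop_moist_forest",
    "Trop_savanna_shrub",
    "Tundra",
]

#: Approximate realm land areas (km^2), used by the demo world.
REALM_AREAS_KM2 = {
    "Afrotropical": 22.1e6,
    "Australasian": 7.7e6,
    "Indomalay": 7.5e6,
    "Nearctic": 22.9e6,
    "Neotropical": 19.0e6,
    "Palaearctic": 54.1e6,
}

# Relative share of the species pool attributed to each region in the
# demo world, loosely mirroring how unevenly a global grass compilation
# spreads over realms (Palaearctic-heavy) and biomes (temperate
# broadleaf-heavy).
_REALM_WEIGHTS = {
    "Palaearctic": 378,
    "Nearctic": 245,
    "Australasian": 270,
    "Afrotropical": 150,
    "Indomalay": 57,
    "Neotropical": 120,
}
_BIOME_WEIGHTS = {
    "Desert": 126,
    "Mediterranean_shrub": 137,
    "Montane_grassland": 73,
    "Taiga": 63,
    "Temp_broadleaf_forest": 393,
    "Temp_coniferous_forest": 76,
    "Temp_savanna_shrub": 159,
    "Trop_coniferous_forest": 19,
    "Trop_dry_forest": 9,
    "Trop_moist_forest": 125,
    "Trop_savanna_shrub": 159,
    "Tundra": 16,
}


def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------
# trees


def simulate_birth_death_tree(
    n_tips: int, birth: float, death: float = 0.0, seed: int = 0
) -> Phylogeny:
    """Constant-rate birth-death tree with exactly ``n_tips`` extant tips.

    Extinct lineages are pruned, so the result is ultrametric and
    strictly bifurcating.  Tips are relabeled ``sp0001`` ... in leaf
    order.  Deterministic given ``seed``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0")
    from dendropy.simulate import treesim

    int_seed = int(np.random.SeedSequence([int(seed), 9001]).generate_state(1)[0])
    tree = treesim.birth_death_tree(
        birth_rate=float(birth),
        death_rate=float(death),
        num_extant_tips=int(n_tips),
        rng=_random.Random(int_seed),
    )
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    tree.seed_node.edge.length = None
    return Phylogeny(tree)


# ---------------------------------------------------------------------
# binary traits


def _check_prevalence(prevalence: int, n: int) -> int:
    prevalence = int(prevalence)
    if not 0 < prevalence < n:
        raise ValueError(f"prevalence must satisfy 0 < k < n_tips (got {prevalence} of {n})")
    return prevalence


def simulate_random_trait(tree: Phylogeny, prevalence: int, seed: int) -> TraitVector:
    """Uniform choice of ``prevalence`` tips without replacement."""
    labels = tree.tip_labels
    prevalence = _check_prevalence(prevalence, len(labels))
    rng = _rng(seed, 1)
    ones = set(rng.choice(len(labels), size=prevalence, replace=False).tolist())
    return TraitVector({lab: int(i in ones) for i, lab in enumerate(labels)}, name="random")


def simulate_threshold_brownian_trait(
    tree: Phylogeny, prevalence: int, seed: int
) -> TraitVector:
    """Brownian-threshold trait: 1 for the ``prevalence`` largest tip values
    of a unit-rate Brownian character evolved along the tree.

    This is the strongly clumped ("neutral evolution") generator: on a
    star tree it degenerates to a uniform random draw, while on a deeply
    structured tree the 1-states concentrate within clades.
    """
    arrays = TreeArrays(tree)
    prevalence = _check_prevalence(prevalence, arrays.n_tips)
    values = arrays.brownian_tip_values(1, _rng(seed, 2))[:, 0]
    states = arrays.threshold_top_k(values, prevalence)
    return TraitVector(
        {lab: int(s) for lab, s in zip(arrays.tip_labels, states)}, name="brownian_threshold"
    )


def simulate_nested_threshold_traits(
    tree: Phylogeny, prevalence_outer: int, prevalence_inner: int, seed: int
) -> tuple[TraitVector, TraitVector]:
    """Two nested Brownian-threshold traits from one Brownian draw.

    The inner trait (e.g. invasive) is a subset of the outer one
    (e.g. naturalized): both threshold the same continuous character at
    different cut ranks, mimicking how invasive species are a listed
    subset of the naturalized pool.
    """
    arrays = TreeArrays(tree)
    k_out = _check_prevalence(prevalence_outer, arrays.n_tips)
    k_in = _check_prevalence(prevalence_inner, arrays.n_tips)
    if k_in > k_out:
        raise ValueError("inner prevalence must not exceed outer prevalence")
    values = arrays.brownian_tip_values(1, _rng(seed, 2))[:, 0]
    outer = arrays.threshold_top_k(values, k_out)
    inner = arrays.threshold_top_k(values, k_in)
    lab = arrays.tip_labels
    return (
        TraitVector({l: int(s) for l, s in zip(lab, outer)}, name="naturalized"),
        TraitVector({l: int(s) for l, s in zip(lab, inner)}, name="invasive"),
    )


def simulate_mk_trait(
    tree: Phylogeny, rate: float, root_state: int = 0, seed: int = 0
) -> TraitVector:
    """Evolve a 2-state equal-rates Markov chain along the tree.

    Over a branch of length t the probability of observing a state
    change is (1 - exp(-2*rate*t)) / 2.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    arrays = TreeArrays(tree)
    rng = _rng(seed, 3)
    p_change = 0.5 - 0.5 * np.exp(-2.0 * rate * arrays.blen)
    flips = rng.random(arrays.n_nodes) < p_change
    states = np.empty(arrays.n_nodes, dtype=np.int8)
    states[0] = root_state
    for i in range(1, arrays.n_nodes):
        states[i] = states[arrays.parent[i]] ^ flips[i]
    return TraitVector(
        {lab: int(states[node]) for lab, node in zip(arrays.tip_labels, arrays.tip_nodes)},
        name="mk",
    )


# ---------------------------------------------------------------------
# regional assemblages and occurrence records


def _subtree_tip_lists(arrays: TreeArrays) -> list[list[int]]:
    lists: list[list[int] | None] = [None] * arrays.n_nodes
    rows = {int(node): r for r, node in enumerate(arrays.tip_nodes)}
    for i in arrays.postorder:
        if arrays.is_tip[i]:
            lists[i] = [rows[int(i)]]
        else:
            acc: list[int] = []
            for c in arrays.children[i]:
                acc.extend(lists[c])
            lists[i] = acc
    return lists  # type: ignore[return-value]


def simulate_regional_assemblages(
    tree: Phylogeny,
    n_regions: int,
    restriction: float,
    richness: int | Sequence[int],
    seed: int,
    region_labels: Sequence[str] | None = None,
) -> pd.Series:
    """Assign species to regions with tunable lineage restriction.

    ``restriction`` interpolates between two mechanisms applied per
    species: with probability ``restriction`` the species is drawn from
    the region's focal clade (chosen as the clade whose available size
    is closest to the requested richness), otherwise uniformly from the
    unassigned pool.  At 0 every region is a uniform sample of the pool
    (a *generalized* factory, SES PD ~ 0 by construction); at 1 each
    region is a single clade (*maximally restricted*).

    Returns a Series mapping species -> region label for assigned
    species (regions are disjoint; leftover species stay unassigned).
    """
    if not 0.0 <= restriction <= 1.0:
        raise ValueError("restriction must lie in [0, 1]")
    arrays = TreeArrays(tree)
    n = arrays.n_tips
    if np.isscalar(richness):
        richness = [int(richness)] * n_regions
    richness = [int(k) for k in richness]
    if len(richness) != n_regions:
        raise ValueError("one richness per region required")
    if any(k < 1 for k in richness):
        raise ValueError("richness must be >= 1")
    if sum(richness) > n:
        raise ValueError(f"total richness {sum(richness)} exceeds pool size {n}")
    if region_labels is None:
        region_labels = [f"region{r + 1}" for r in range(n_regions)]
    if len(region_labels) != n_regions:
        raise ValueError("one label per region required")

    rng = _rng(seed, 4)
    labels = arrays.tip_labels
    clades = [l for l in _subtree_tip_lists(arrays) if len(l) > 1]
    available = np.ones(n, dtype=bool)
    assignment: dict[str, str] = {}
    for region, k in zip(region_labels, richness):
        focal: list[int] = []
        if restriction > 0:
            sizes = np.array([np.count_nonzero(available[c]) for c in clades])
            usable = np.flatnonzero(sizes > 0)
            gap = np.abs(sizes[usable] - k)
            best = usable[gap == gap.min()]
            if gap.min() > 0:
                logger.info(
                    "region %s: no available clade of size %d; nearest is %d",
                    region, k, int(sizes[best[0]]),
                )
            chosen = int(rng.choice(best))
            focal = [t for t in clades[chosen] if available[t]]
        members: list[int] = []
        for _ in range(k):
            pick = None
            if restriction > 0 and rng.random() < restriction and focal:
                pick = int(focal[rng.integers(len(focal))])
            else:
                pool = np.flatnonzero(available)
                pick = int(pool[rng.integers(len(pool))])
            members.append(pick)
            available[pick] = False
            focal = [t for t in focal if available[t]]
        for t in members:
            assignment[labels[t]] = region
    return pd.Series(assignment, name="region")


def simulate_occurrences(
    assignments: pd.DataFrame | pd.Series,
    n_records: int,
    noise: float,
    seed: int,
    realm_labels: Sequence[str] | None = None,
    biome_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Noisy occurrence records from true per-species region labels.

    ``assignments``: DataFrame with columns ``realm`` and/or ``biome``
    indexed by species (a Series is treated as a realm column).  Each
    species gets ``n_records`` records; each record's label equals the
    true label with probability 1 - noise, otherwise a uniformly chosen
    *other* label from the label set.  Realm and biome errors are
    independent.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    if isinstance(assignments, pd.Series):
        assignments = assignments.to_frame("realm")
    levels = [c for c in ("realm", "biome") if c in assignments.columns]
    if not levels:
        raise ValueError("assignments must have a 'realm' and/or 'biome' column")
    label_sets = {
        "realm": list(realm_labels) if realm_labels is not None
        else sorted(assignments["realm"].unique()) if "realm" in levels else [],
        "biome": list(biome_labels) if biome_labels is not None
        else sorted(assignments["biome"].unique()) if "biome" in levels else [],
    }
    rng = _rng(seed, 5)
    rows: dict[str, list] = {"species": []}
    for level in levels:
        rows[level] = []
    for species, row in assignments.sort_index().iterrows():
        rows["species"].extend([species] * n_records)
        for level in levels:
            true = row[level]
            labels = label_sets[level]
            out = np.full(n_records, true, dtype=object)
            if len(labels) > 1 and noise > 0:
                err = rng.random(n_records) < noise
                others = [l for l in labels if l != true]
                if err.any():
                    out[err] = rng.choice(others, size=int(err.sum()))
            rows[level].extend(out.tolist())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# full synthetic world


@dataclass
class SyntheticWorld:
    """A complete, internally consistent synthetic data set."""

    tree: Phylogeny
    status: pd.DataFrame  # species, naturalized, invasive
    regions: pd.DataFrame  # species-indexed: realm, biome (the truth)
    occurrences: pd.DataFrame  # species, realm, biome (one row per record)
    clades: pd.DataFrame  # species, clade
    areas: pd.DataFrame  # region, area_km2
    params: dict = field(default_factory=dict)

    @property
    def naturalized(self) -> TraitVector:
        return TraitVector.from_series(
            self.status.set_index("species")["naturalized"], name="naturalized"
        )

    @property
    def invasive(self) -> TraitVector:
        return TraitVector.from_series(
            self.status.set_index("species")["invasive"], name="invasive"
        )

    def write(self, out_dir) -> dict[str, str]:
        """Write the world in the pipeline's input formats; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": out / "tree.nwk",
            "status": out / "status.csv",
            "occurrences": out / "occurrences.csv",
            "clades": out / "clades.csv",
            "areas": out / "areas.csv",
            "truth": out / "truth.json",
        }
        self.tree.write(paths["tree"])
        self.status.to_csv(paths["status"], index=False)
        self.occurrences.to_csv(paths["occurrences"], index=False)
        self.clades.to_csv(paths["clades"], index=False)
        self.areas.to_csv(paths["areas"], index=False)
        import json

        truth = {
            "params": self.params,
            "true_regions": {
                sp: {"realm": r["realm"], "biome": r["biome"]}
                for sp, r in self.regions.iterrows()
            },
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        return {k: str(v) for k, v in paths.items()}


def _proportional_richness(n: int, weights: dict[str, int]) -> dict[str, int]:
    """Largest-remainder split of n species over regions by weight."""
    total = sum(weights.values())
    raw = {k: n * w / total for k, w in weights.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(base.values())
    order = sorted(weights, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:short]:
        base[k] += 1
    return {k: v for k, v in base.items() if v > 0}


def generate_world(
    seed: int,
    n_tips: int = 200,
    birth: float = 1.0,
    death: float = 0.0,
    prevalence_naturalized: float = 0.365,
    prevalence_invasive: float = 0.186,
    restriction: float = 0.7,
    n_records: int = 30,
    noise: float = 0.2,
) -> SyntheticWorld:
    """Generate the default synthetic world.

    Defaults emulate the empirical setting the pipeline targets: about
    36.5% of species naturalized with an invasive subset of ~18.6%
    (thresholds of one shared Brownian character, so the invasive set
    nests inside the naturalized one and both are phylogenetically
    clumped), six realms and twelve biomes partitioning the species
    pool with realistically uneven richness, moderate lineage
    restriction per region, and 30 occurrence records per species at
    20% label noise.
    """
    tree = simulate_birth_death_tree(n_tips, birth=birth, death=death, seed=seed)
    k_nat = max(2, int(round(prevalence_naturalized * n_tips)))
    k_inv = max(1, int(round(prevalence_invasive * n_tips)))
    nat, inv = simulate_nested_threshold_traits(tree, k_nat, k_inv, seed)
    labels = tree.tip_labels
    status = pd.DataFrame(
        {
            "species": labels,
            "naturalized": [nat[l] for l in labels],
            "invasive": [inv[l] for l in labels],
        }
    )

    realm_rich = _proportional_richness(n_tips, _REALM_WEIGHTS)
    realm_assign = simulate_regional_assemblages(
        tree,
        n_regions=len(realm_rich),
        restriction=restriction,
        richness=list(realm_rich.values()),
        seed=seed,
        region_labels=list(realm_rich.keys()),
    )
    biome_rich = _proportional_richness(n_tips, _BIOME_WEIGHTS)
    biome_assign = simulate_regional_assemblages(
        tree,
        n_regions=len(biome_rich),
        restriction=restriction,
        richness=list(biome_rich.values()),
        seed=seed + 1,
        region_labels=list(biome_rich.keys()),
    )
    regions = pd.DataFrame({"realm": realm_assign, "biome": biome_assign}).dropna()
    regions.index.name = "species"
    occurrences = simulate_occurrences(
        regions,
        n_records=n_records,
        noise=noise,
        seed=seed,
        realm_labels=list(realm_rich.keys()),
        biome_labels=list(biome_rich.keys()),
    )

    # two clade partitions from the basal split, for subclade analyses
    root_children = tree.dendropy_tree.seed_node.child_nodes()
    clade_of: dict[str, str] = {}
    for ci, child in enumerate(root_children):
        name = "cladeA" if ci == 0 else "cladeB"
        for leaf in child.leaf_iter():
            clade_of[leaf.taxon.label] = name
    clades = pd.DataFrame(
        {"species": labels, "clade": [clade_of[l] for l in labels]}
    )

    areas = pd.DataFrame(
        {"region": list(REALM_AREAS_KM2), "area_km2": list(REALM_AREAS_KM2.values())}
    )
    params = {
        "seed": int(seed),
        "n_tips": int(n_tips),
        "birth": birth,
        "death": death,
        "prevalence_naturalized": prevalence_naturalized,
        "prevalence_invasive": prevalence_invasive,
        "clumping_mode": "brownian_threshold_nested",
        "restriction": restriction,
        "n_records": int(n_records),
        "noise": noise,
    }
    return SyntheticWorld(
        tree=tree,
        status=status,
        regions=regions,
        occurrences=occurrences,
        clades=clades,
        areas=areas,
        params=params,
    )
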