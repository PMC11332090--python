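"""Source-region assignment, alien ratios, Faith's PD and SES PD.

Species are attributed to the biogeographic realm and biome where most
of their occurrence records fall (the record mode, computed
independently per level).  Per region the module tabulates alien
counts and percentages, Faith's phylogenetic diversity of the regional
alien assemblage, and the standardized effect size of that PD against
richness-matched random assemblages drawn from a species pool — the
test separating *generalized* factories (alien PD indistinguishable
from random draws) from *restrictive* ones (alien PD significantly
low, i.e. lineage-restricted export).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._arrays import TreeArrays
from .treeio import Phylogeny

__all__ = [
    "SESPDResult",
    "assign_region_mode",
    "alien_ratio_table",
    "faith_pd",
    "ses_pd",
    "normalize_by_area",
]

logger = logging.getLogger(__name__)


def assign_region_mode(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Modal realm and biome per species from occurrence records.

    ``occurrences`` has one row per record with columns ``species`` and
    one or both of ``realm``/``biome``.  Ties on the modal count are
    broken by lexicographic label order and flagged.  Returns a
    species-indexed frame with, per available level, the modal label, a
    tie flag, and the total record count.
    """
    if occurrences.empty:
        raise ValueError("occurrence table is empty")
    levels = [c for c in ("realm", "biome") if c in occurrences.columns]
    if "species" not in occurrences.columns or not levels:
        raise ValueError("occurrences need a 'species' column and a 'realm'/'biome' column")
    out: dict[str, pd.Series] = {}
    for level in levels:
        counts = (
            occurrences.groupby(["species", level], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
        counts = counts.sort_values(["species", "n", level],
                                    ascending=[True, False, True], kind="stable")
        top = counts.groupby("species", observed=True).first()
        nmax = counts.groupby("species", observed=True)["n"].max()
        n_at_max = counts[counts["n"].values == nmax.loc[counts["species"]].values]
        ties = n_at_max.groupby("species", observed=True).size() > 1
        out[level] = top[level]
        out[f"{level}_tie"] = ties
    out["n_records"] = occurrences.groupby("species", observed=True).size()
    result = pd.DataFrame(out)
    result.index.name = "species"
    for level in levels:
        n_tied = int(result[f"{level}_tie"].sum())
        if n_tied:
            logger.info("%d species had tied modal %s labels (lexicographic break)",
                        n_tied, level)
    return result.sort_index()


def alien_ratio_table(
    assignments: pd.DataFrame, status: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Per-region totals, alien counts and alien percentages.

    ``assignments`` is the species-indexed output of
    :func:`assign_region_mode` (or a truth table with the same columns);
    ``status`` has columns species/naturalized/invasive.  Percentages
    are recomputed from the counts and rounded to one decimal.
    """
    if level not in ("realm", "biome"):
        raise ValueError("level must be 'realm' or 'biome'")
    st = status.set_index("species")[["naturalized", "invasive"]]
    joined = assignments[[level]].join(st, how="inner")
    dropped = len(assignments) - len(joined)
    if dropped:
        logger.info("%d assigned species missing from the status table; excluded", dropped)
    grouped = joined.groupby(level, observed=True)
    table = pd.DataFrame(
        {
            "total": grouped.size(),
            "naturalized": grouped["naturalized"].sum().astype(int),
            "invasive": grouped["invasive"].sum().astype(int),
        }
    )
    table = table[table["total"] > 0]
    table["pct_naturalized"] = (100.0 * table["naturalized"] / table["total"]).round(1)
    table["pct_invasive"] = (100.0 * table["invasive"] / table["total"]).round(1)
    table.index.name = level
    return table.sort_index()


def faith_pd(tree: Phylogeny, assemblage, include_root: bool = True) -> float:
    """Faith's PD: total branch length of the union of root-to-tip paths
    of the assemblage (root path included by default; with
    ``include_root=False`` only the minimal subtree connecting the tips
    is counted)."""
    species = list(dict.fromkeys(assemblage))
    if not species:
        raise ValueError("empty assemblage")
    mapping = tree.resolve_names(species)  # KeyError names unknown species
    arrays = TreeArrays(tree)
    rows = arrays.tip_rows([mapping[s] for s in species])
    ind = np.zeros(arrays.n_tips, dtype=np.int8)
    ind[rows] = 1
    return float(arrays.pd_values(ind, include_root=include_root))


@dataclass(frozen=True)
class SESPDResult:
    """SES-PD of one regional assemblage against one null pool."""

    region: str
    trait: str
    pool: str  # "global" | "regional" | caller-supplied label
    richness: int
    pd_obs: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_null: int
    verdict: str  # "generalized" | "restrictive" | "indeterminate"
    seed: int


def ses_pd(
    tree: Phylogeny,
    assemblage,
    pool,
    n_null: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    include_root: bool = True,
    region: str = "region",
    trait: str = "trait",
    pool_label: str = "global",
) -> SESPDResult:
    """Standardized effect size of Faith's PD against richness-matched nulls.

    Null assemblages are uniform samples, without replacement, of the
    observed richness from ``pool``; p = (1 + #{null PD <= observed PD})
    / (n_null + 1), small when the assemblage is less phylodiverse than
    random (lineage-restricted).  Verdict: "restrictive" when p < alpha,
    otherwise "generalized"; assemblages of fewer than 3 species are
    labelled "indeterminate".  Deterministic given seed.
    """
    species = list(dict.fromkeys(assemblage))
    pool = list(dict.fromkeys(pool))
    k = len(species)
    if k < 1:
        raise ValueError("empty assemblage")
    if not set(species) <= set(pool):
        raise ValueError("assemblage must be a subset of the pool")
    if k >= len(pool):
        raise ValueError(
            "assemblage size equals the pool size: the null is degenerate; "
            "use a strictly larger pool"
        )
    mapping = tree.resolve_names(pool)
    arrays = TreeArrays(tree)
    pool_rows = arrays.tip_rows([mapping[s] for s in pool])
    obs_rows = arrays.tip_rows([mapping[s] for s in species])

    ind = np.zeros(arrays.n_tips, dtype=np.int8)
    ind[obs_rows] = 1
    pd_obs = float(arrays.pd_values(ind, include_root=include_root))

    rng = np.random.default_rng([int(seed), 7])
    nulls = np.zeros((arrays.n_tips, n_null), dtype=np.int8)
    for j in range(n_null):
        pick = rng.choice(pool_rows, size=k, replace=False)
        nulls[pick, j] = 1
    null_pd = arrays.pd_values(nulls, include_root=include_root)
    null_mean = float(null_pd.mean())
    null_sd = float(null_pd.std(ddof=1))
    if null_sd > 0:
        ses = (pd_obs - null_mean) / null_sd
    else:
        ses = float("nan")
        logger.warning("null PD has zero spread for region %s; SES undefined", region)
    p = float((1 + int(np.sum(null_pd <= pd_obs))) / (n_null + 1))
    if k < 3:
        verdict = "indeterminate"
    elif p < alpha:
        verdict = "restrictive"
    else:
        verdict = "generalized"
    return SESPDResult(
        region=str(region), trait=str(trait), pool=str(pool_label), richness=k,
        pd_obs=pd_obs, null_mean=null_mean, null_sd=null_sd, ses=float(ses),
        p_value=p, n_null=int(n_null), verdict=verdict, seed=int(seed),
    )


def normalize_by_area(
    counts: pd.Series | dict, areas: pd.DataFrame | pd.Series | dict, per: float = 1e6
) -> pd.Series:
    """Counts per unit area (default: species per 10^6 km^2)."""
    counts = pd.Series(counts, dtype=float)
    if isinstance(areas, pd.DataFrame):
        areas = areas.set_index("region")["area_km2"]
    areas = pd.Series(areas, dtype=float)
    missing = [r for r in counts.index if r not in areas.index or not areas[r] > 0]
    if missing:
        raise ValueError(f"missing or non-positive area for regions: {sorted(missing)}")
    out = counts / areas.loc[counts.index] * per
    out.name = "density"
    return out
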