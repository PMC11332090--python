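"""End-to-end orchestration: config, staged analysis, synthetic demo.

:func:`run_full_analysis` executes, in order: tree loading — clumping
D per clade and trait — Mk fit and marginal ancestral states — tip
rates and phylogenetic logistic regression — region assignment, ratio
and PD tables — SES PD against the global and regional pools.  All
randomness fans out derivably from a single master seed, so a rerun
with an identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestral, biogeo, divreg, io, signal, synthetic
from .treeio import Phylogeny, read_newick

__all__ = ["RunConfig", "run_full_analysis", "demo_generate"]

logger = logging.getLogger(__name__)

_STAGE_STREAMS = {"signal": 11, "ancestral": 12, "divreg": 13, "sespd": 14}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed (stable, < 2^31)."""
    stream = _STAGE_STREAMS.get(stage, 99)
    state = np.random.SeedSequence([int(master_seed), stream]).generate_state(1)[0]
    return int(state % (2**31 - 1))


@dataclass
class RunConfig:
    """Paths, parameters and toggles for a full run."""

    tree: str
    status: str
    occurrences: str | None = None
    clades: str | None = None
    rates: str | None = None
    areas: str | None = None
    out_dir: str = "results"
    traits: tuple[str, ...] = ("naturalized", "invasive")
    n_perm: int = 1000
    n_null: int = 100
    alpha: float = 0.05
    seed: int = 0
    include_root_pd: bool = True
    pools: tuple[str, ...] = ("global", "regional")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("traits", "pools"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        for name in ("tree", "status", "occurrences", "clades", "rates", "areas"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config.{name}: no such file: {path}")
        if self.n_perm < 1 or self.n_null < 1:
            raise ValueError("n_perm and n_null must be >= 1")
        bad = set(self.traits) - {"naturalized", "invasive"}
        if bad:
            raise ValueError(f"unknown traits: {sorted(bad)}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str, index: bool):
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n# config: {cfg_hash}\n")
        df.to_csv(fh, index=index)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Any stage failure halts the run with the stage name; the manifest
    written so far is saved as ``manifest.partial.json``.
    """
    config.validate()
    cfg_hash = config.config_hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": cfg_hash,
        "versions": _versions(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_STREAMS},
        "outputs": [],
        "log": [],
    }

    stage = "load"
    try:
        tree = read_newick(config.tree)
        status = io.read_status_table(config.status)
        known = tree.resolve_names(status["species"])
        status = status.assign(species=status["species"].map(known))
        manifest["log"].append(f"loaded tree with {tree.n_tips} tips")

        # ---- clumping signal (one row per clade x trait) -------------
        stage = "signal"
        rows = []
        clade_members = {"all": list(tree.tip_labels)}
        if config.clades:
            cl = io.read_clades(config.clades)
            mapping = tree.resolve_names(cl["species"])
            for name, grp in cl.groupby("clade"):
                clade_members[str(name)] = [mapping[s] for s in grp["species"]]
        sseed = stage_seed(config.seed, "signal")
        for trait_name in config.traits:
            trait = io.trait_from_status(status, trait_name)
            for clade, members in clade_members.items():
                sub = tree if clade == "all" else tree.prune_to_taxa(members)
                tr = trait.restricted_to(sub.tip_labels)
                if tr.is_invariant() or sub.n_tips < 4:
                    manifest["log"].append(
                        f"signal: skipped clade {clade} x {trait_name} "
                        "(invariant trait or too few tips)"
                    )
                    continue
                res = signal.estimate_D(sub, tr, n_perm=config.n_perm, seed=sseed,
                                        clade=clade)
                verdicts = {
                    "verdict_brownian": "Reject" if res.p_brownian < config.alpha
                    else "Evidence",
                    "verdict_random": "Reject" if res.p_random < config.alpha
                    else "Evidence",
                    "scenario": signal.interpret_D(res, alpha=config.alpha),
                }
                rows.append({**dataclasses.asdict(res), **verdicts})
        d_table = pd.DataFrame(rows)
        _write_csv(d_table, out / "clumping_d.csv", "signal", cfg_hash, index=False)
        manifest["outputs"].append("clumping_d.csv")

        # ---- ancestral states ----------------------------------------
        stage = "ancestral"
        trait = io.trait_from_status(status, config.traits[-1])
        res_tree = tree.resolve_polytomies(stage_seed(config.seed, "ancestral"))
        fit = ancestral.fit_mk_er(res_tree, trait)
        states = ancestral.marginal_ancestral_states(res_tree, trait, fit)
        anc = pd.DataFrame(
            {
                "node": list(states.probs),
                "p0": [p[0] for p in states.probs.values()],
                "p1": [p[1] for p in states.probs.values()],
                "n_tips_below": [len(states.tip_sets[n]) for n in states.probs],
            }
        )
        anc["q_hat"] = fit.rate
        anc["loglik"] = fit.loglik
        _write_csv(anc, out / "ancestral_nodes.csv", "ancestral", cfg_hash, index=False)
        manifest["outputs"].append("ancestral_nodes.csv")

        # ---- diversification regression ------------------------------
        stage = "divreg"
        rates = (
            divreg.read_tip_rates(config.rates, tree=tree)
            if config.rates
            else divreg.equal_splits_rates(tree)
        )
        inv = io.trait_from_status(status, "invasive")
        glm = divreg.fit_phylo_logistic(tree, inv, rates)
        with open(out / "divreg.json", "w") as fh:
            json.dump(
                {**dataclasses.asdict(glm), "rates_source": rates.source,
                 "stage": "divreg", "config": cfg_hash},
                fh, indent=2, sort_keys=True,
            )
        manifest["outputs"].append("divreg.json")

        # ---- biogeography --------------------------------------------
        if config.occurrences:
            stage = "biogeo"
            occ = io.read_occurrences(config.occurrences)
            assignments = biogeo.assign_region_mode(occ)
            zero = assignments[assignments["n_records"] < 1]
            if len(zero):
                manifest["log"].append(f"biogeo: {len(zero)} species without records")
            levels = [c for c in ("realm", "biome") if c in assignments.columns]
            status_idx = status.set_index("species")
            bseed = stage_seed(config.seed, "sespd")
            ses_rows = []
            for level in levels:
                table = biogeo.alien_ratio_table(assignments, status, level)
                pd_nat, pd_inv = [], []
                for region in table.index:
                    members = assignments.index[assignments[level] == region]
                    members = [m for m in members if m in status_idx.index]
                    nat = [m for m in members if status_idx.loc[m, "naturalized"] == 1]
                    invs = [m for m in members if status_idx.loc[m, "invasive"] == 1]
                    pd_nat.append(biogeo.faith_pd(tree, nat, config.include_root_pd)
                                  if nat else 0.0)
                    pd_inv.append(biogeo.faith_pd(tree, invs, config.include_root_pd)
                                  if invs else 0.0)
                    for trait_name in config.traits:
                        assemblage = nat if trait_name == "naturalized" else invs
                        for pool_label in config.pools:
                            pool = (list(tree.tip_labels) if pool_label == "global"
                                    else list(members))
                            if not (1 <= len(assemblage) < len(pool)):
                                manifest["log"].append(
                                    f"sespd: skipped {level}={region} {trait_name} "
                                    f"pool={pool_label} (degenerate sizes)"
                                )
                                continue
                            r = biogeo.ses_pd(
                                tree, assemblage, pool, n_null=config.n_null,
                                seed=bseed, alpha=config.alpha,
                                include_root=config.include_root_pd,
                                region=region, trait=trait_name,
                                pool_label=pool_label,
                            )
                            ses_rows.append(dataclasses.asdict(r))
                table["pd_naturalized"] = np.round(pd_nat, 4)
                table["pd_invasive"] = np.round(pd_inv, 4)
                if config.areas and level == "realm":
                    areas = io.read_areas(config.areas)
                    try:
                        dens = biogeo.normalize_by_area(table["invasive"], areas)
                        table["invasive_per_Mkm2"] = dens.round(4)
                    except ValueError as exc:
                        manifest["log"].append(f"biogeo: area normalization skipped ({exc})")
                _write_csv(table, out / f"{level}_table.csv", "biogeo", cfg_hash,
                           index=True)
                manifest["outputs"].append(f"{level}_table.csv")
            ses_df = pd.DataFrame(ses_rows)
            _write_csv(ses_df, out / "ses_pd.csv", "biogeo", cfg_hash, index=False)
            manifest["outputs"].append("ses_pd.csv")

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        manifest["outputs"].append("manifest.json")
        return manifest
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.partial.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def _versions() -> dict:
    import dendropy
    import scipy

    from . import __version__

    return {
        "phylofactory": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "dendropy": dendropy.__version__,
    }


def demo_generate(seed: int, out_dir, **world_kwargs) -> dict[str, str]:
    """Write a complete synthetic input set (tree + tables + truth file)."""
    world = synthetic.generate_world(seed, **world_kwargs)
    return world.write(out_dir)
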