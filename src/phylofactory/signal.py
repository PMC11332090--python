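"""Phylogenetic clumping of a binary trait: the D statistic with dual nulls.

The raw quantity d is the sum, over all edges of a bifurcating tree, of
the absolute difference between parent and child nodal trait values,
where tips carry their 0/1 states and each internal node the unweighted
mean of its two daughters.  A clumped trait changes along few edges and
yields small d; a dispersed trait yields large d.

D rescales d between two simulated expectations at the observed
prevalence:

    D = (d_obs - mean d under Brownian-threshold simulation)
        / (mean d under random tip shuffles - Brownian mean)

so D ~ 1 means the trait looks like a random scatter over tips and
D ~ 0 means it is as clumped as a thresholded Brownian character.  Each
null also yields a one-sided permutation p-value; the pair of p-values
maps onto four scenarios (random-consistent, Brownian-consistent,
intermediate clumping, inconclusive).

Nodal values here use the plain daughter mean, ignoring branch lengths.
Contrast-based weightings exist; because observed and null d are
computed with the identical operator the rescaling is self-normalizing
(E[D] ~ 1 / ~ 0 under the matching generators), which is the
correctness criterion adopted here.  Numerical parity with any
particular alternative weighting is therefore not expected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._arrays import TreeArrays
from .traits import TraitVector
from .treeio import Phylogeny

__all__ = ["DResult", "sum_sister_differences", "estimate_D", "interpret_D"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DResult:
    """One row of a clumping analysis (one clade x one trait)."""

    clade: str
    trait: str
    n_tips: int
    prevalence: int
    d_obs: float
    d_random_mean: float
    d_brownian_mean: float
    D: float
    p_random: float
    p_brownian: float
    n_perm: int
    seed: int


def _as_arrays(tree: Phylogeny, seed: int = 0) -> TreeArrays:
    if not tree.is_bifurcating:
        logger.info("resolving polytomies (zero-length, seed=%d) before computing d", seed)
        tree = tree.resolve_polytomies(seed)
    return TreeArrays(tree)


def sum_sister_differences(tree: Phylogeny, traits: TraitVector) -> float:
    """Observed d: one post-order averaging pass, then the edge-wise sum
    of absolute parent-child differences.  Requires (or resolves to) a
    bifurcating tree; invariant to tip listing order."""
    arrays = _as_arrays(tree)
    values = traits.aligned(tree)  # validates coverage, names any missing tip
    by_tip = dict(zip(tree.tip_labels, values))
    ordered = np.asarray([by_tip[lab] for lab in arrays.tip_labels], dtype=float)
    return float(arrays.sister_diff_sums(ordered))


def estimate_D(
    tree: Phylogeny,
    traits: TraitVector,
    n_perm: int = 1000,
    seed: int = 0,
    clade: str = "all",
) -> DResult:
    """Estimate D with random-permutation and Brownian-threshold nulls.

    p_random is the probability, under tip shuffles, of a null d at or
    below the observed one (small = more clumped than random);
    p_brownian is the probability, under Brownian-threshold simulation,
    of a null d at or above the observed one (small = more dispersed
    than Brownian).  Both use the add-one permutation convention.
    Deterministic given (inputs, seed, n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if traits.is_invariant():
        raise ValueError("trait invariant; D undefined")
    resolved = tree.resolve_polytomies(seed) if not tree.is_bifurcating else tree
    arrays = TreeArrays(resolved)
    if arrays.n_tips < 4:
        raise ValueError("D requires at least 4 tips")
    obs = traits.aligned(resolved).astype(float)
    k = int(obs.sum())
    d_obs = float(arrays.sister_diff_sums(obs))

    rng = np.random.default_rng([int(seed), 101])
    perms = np.empty((arrays.n_tips, n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(obs)
    d_random = arrays.sister_diff_sums(perms)

    brng = np.random.default_rng([int(seed), 102])
    bvals = arrays.brownian_tip_values(n_perm, brng)
    bstates = arrays.threshold_top_k(bvals, k).astype(float)
    d_brownian = arrays.sister_diff_sums(bstates)

    mean_r = float(d_random.mean())
    mean_b = float(d_brownian.mean())
    if np.isclose(mean_r, mean_b):
        raise ValueError(
            "degenerate nulls: random and Brownian expectations coincide; D undefined"
        )
    D = (d_obs - mean_b) / (mean_r - mean_b)
    p_random = (1 + int(np.sum(d_random <= d_obs))) / (n_perm + 1)
    p_brownian = (1 + int(np.sum(d_brownian >= d_obs))) / (n_perm + 1)
    return DResult(
        clade=clade,
        trait=traits.name,
        n_tips=arrays.n_tips,
        prevalence=k,
        d_obs=d_obs,
        d_random_mean=mean_r,
        d_brownian_mean=mean_b,
        D=float(D),
        p_random=float(p_random),
        p_brownian=float(p_brownian),
        n_perm=int(n_perm),
        seed=int(seed),
    )


#: Scenario labels for the four hypothesis-test outcomes.
SCENARIOS = {
    (True, True): "intermediate clumping",
    (True, False): "Brownian-consistent",
    (False, True): "random-consistent",
    (False, False): "inconclusive",
}


def interpret_D(result: DResult, alpha: float = 0.05) -> str:
    """Map the two null tests onto the four-scenario framework.

    Rejecting the random null alone supports Brownian-like clumping;
    rejecting the Brownian null alone supports random emergence;
    rejecting both indicates intermediate clumping; rejecting neither is
    inconclusive.
    """
    reject_random = result.p_random < alpha
    reject_brownian = result.p_brownian < alpha
    return SCENARIOS[(reject_random, reject_brownian)]
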