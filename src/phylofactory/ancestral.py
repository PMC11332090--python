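"""Equal-rates Mk model: likelihood, rate fit, marginal ancestral states.

The 2-state equal-rates Mk model is a continuous-time Markov chain with
a single transition rate q; over a branch of length t,

    P(same state) = 1/2 + exp(-2 q t) / 2
    P(change)     = 1/2 - exp(-2 q t) / 2.

The likelihood is computed by Felsenstein's pruning algorithm with the
stationary root prior (1/2, 1/2); marginal ancestral probabilities are
obtained by combining the partial likelihoods below each node with the
likelihood of the rest of the tree above it, which is algebraically the
re-rooting construction for marginal reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ._arrays import TreeArrays
from .traits import TraitVector
from .treeio import Phylogeny

__all__ = [
    "MkFit",
    "AncestralStates",
    "mk_transition_probability",
    "mk_loglik",
    "fit_mk_er",
    "marginal_ancestral_states",
]

ROOT_PRIOR = np.array([0.5, 0.5])


class ZeroLikelihoodError(FloatingPointError):
    """The observed states have probability zero under the model
    (possible when zero-length branches separate conflicting tips)."""


@dataclass(frozen=True)
class MkFit:
    rate: float
    loglik: float
    converged: bool
    at_bound: bool = False


@dataclass(frozen=True)
class AncestralStates:
    """Marginal state probabilities for internal nodes.

    ``probs`` maps a node id (``"N<i>"`` in preorder numbering, ``"N0"``
    the root) to (P(state 0), P(state 1)); ``tip_sets`` gives the tip
    labels below each node so ids can be matched structurally.
    """

    probs: dict[str, tuple[float, float]]
    tip_sets: dict[str, frozenset[str]]
    fit: MkFit

    def __getitem__(self, node_id: str) -> tuple[float, float]:
        return self.probs[node_id]


def mk_transition_probability(rate: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the equal-rates chain over a branch."""
    if rate < 0 or t < 0:
        raise ValueError("rate and branch length must be non-negative")
    same = 0.5 + 0.5 * np.exp(-2.0 * rate * t)
    change = 1.0 - same
    return np.array([[same, change], [change, same]])


def _tip_partials(arrays: TreeArrays, tree: Phylogeny, traits: TraitVector) -> np.ndarray:
    values = traits.aligned(tree)
    by_tip = dict(zip(tree.tip_labels, values))
    partials = np.zeros((arrays.n_nodes, 2))
    for row, node in enumerate(arrays.tip_nodes):
        state = by_tip[arrays.tip_labels[row]]
        partials[node, int(state)] = 1.0
    return partials


def _prune(arrays: TreeArrays, partials: np.ndarray, rate: float):
    """Post-order pruning pass with per-node scaling.

    Returns (down, log_scale) where ``down[i]`` is the scaled partial
    likelihood of the data below node i given its state, and
    ``log_scale`` the accumulated log of the scaling factors.
    """
    down = partials.copy()
    trans = [None] * arrays.n_nodes
    for i in range(1, arrays.n_nodes):
        trans[i] = mk_transition_probability(rate, arrays.blen[i])
    log_scale = 0.0
    for i in arrays.postorder:
        ch = arrays.children[i]
        if not ch:
            continue
        acc = np.ones(2)
        for c in ch:
            acc = acc * (trans[c] @ down[c])
        norm = acc.sum()
        if norm <= 0:
            raise ZeroLikelihoodError(
                "zero partial likelihood: data impossible under the model"
            )
        log_scale += np.log(norm)
        down[i] = acc / norm
    return down, log_scale, trans


def mk_loglik(tree: Phylogeny, traits: TraitVector, rate: float) -> float:
    """Log-likelihood of the trait under the equal-rates Mk model."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    arrays = TreeArrays(tree)
    partials = _tip_partials(arrays, tree, traits)
    try:
        down, log_scale, _ = _prune(arrays, partials, rate)
    except ZeroLikelihoodError:
        return float("-inf")
    return float(np.log(ROOT_PRIOR @ down[0]) + log_scale)


def fit_mk_er(
    tree: Phylogeny, traits: TraitVector, bracket: tuple[float, float] | None = None
) -> MkFit:
    """Maximum-likelihood transition rate by bounded 1-D search.

    The default bracket is [1e-8, 100 / tree height].  An invariant
    trait drives the optimum to the lower bound; the fit is returned
    with ``at_bound`` set rather than raising.
    """
    arrays = TreeArrays(tree)
    partials = _tip_partials(arrays, tree, traits)
    height = max(arrays.height, np.finfo(float).tiny)
    lo, hi = bracket if bracket is not None else (1e-8, 100.0 / height)

    def neg_loglik(q: float) -> float:
        try:
            down, log_scale, _ = _prune(arrays, partials, q)
        except ZeroLikelihoodError:
            return float("inf")
        return -(np.log(ROOT_PRIOR @ down[0]) + log_scale)

    res = minimize_scalar(neg_loglik, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:  # pragma: no cover - scipy bounded rarely fails
        raise RuntimeError(f"Mk rate optimization failed: {res.message}")
    q_hat = float(res.x)
    at_bound = bool(q_hat <= lo * (1 + 1e-6) or traits.is_invariant())
    return MkFit(rate=q_hat, loglik=float(-res.fun), converged=bool(res.success),
                 at_bound=at_bound)


def marginal_ancestral_states(
    tree: Phylogeny, traits: TraitVector, fit: MkFit | float
) -> AncestralStates:
    """Marginal state probabilities at every internal node.

    For node v the marginal is proportional to the product of the
    pruning partial below v and the "outside" message passed down from
    the root (which carries the prior), normalized to sum to 1 — the
    re-rooting construction evaluated in one up-down sweep.
    """
    mkfit = fit if isinstance(fit, MkFit) else MkFit(rate=float(fit), loglik=np.nan,
                                                    converged=True)
    if mkfit.rate < 0:
        raise ValueError("rate must be >= 0")
    arrays = TreeArrays(tree)
    partials = _tip_partials(arrays, tree, traits)
    down, _, trans = _prune(arrays, partials, mkfit.rate)

    up = np.zeros((arrays.n_nodes, 2))
    up[0] = ROOT_PRIOR
    for i in arrays.preorder:
        ch = arrays.children[i]
        if not ch:
            continue
        msgs = {c: trans[c] @ down[c] for c in ch}
        for c in ch:
            outside = up[i].copy()
            for s in ch:
                if s is not c:
                    outside = outside * msgs[s]
            vec = trans[c].T @ outside
            norm = vec.sum()
            up[c] = vec / norm if norm > 0 else ROOT_PRIOR

    probs: dict[str, tuple[float, float]] = {}
    tip_sets: dict[str, frozenset[str]] = {}
    below: list[set[str] | None] = [None] * arrays.n_nodes
    rows = {int(node): lab for node, lab in zip(arrays.tip_nodes, arrays.tip_labels)}
    for i in arrays.postorder:
        if arrays.is_tip[i]:
            below[i] = {rows[int(i)]}
        else:
            acc: set[str] = set()
            for c in arrays.children[i]:
                acc |= below[c]
            below[i] = acc
    for i in arrays.preorder:
        if arrays.is_tip[i]:
            continue
        joint = down[i] * up[i]
        total = joint.sum()
        if total <= 0:
            raise FloatingPointError(f"degenerate marginal at node N{i}")
        p = joint / total
        probs[f"N{i}"] = (float(p[0]), float(p[1]))
        tip_sets[f"N{i}"] = frozenset(below[i])
    return AncestralStates(probs=probs, tip_sets=tip_sets, fit=mkfit)
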