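"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by direct enumeration or
naive recursion over the dendropy tree, deliberately sharing no code
with the array-based implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def d_bruteforce(phylo, states: dict) -> float:
    """Sister-difference sum by naive recursion (bifurcating trees)."""
    tree = phylo.dendropy_tree
    vals: dict[int, float] = {}

    def value(node) -> float:
        if node.is_leaf():
            v = float(states[node.taxon.label])
        else:
            ch = node.child_nodes()
            assert len(ch) == 2, "oracle requires a bifurcating tree"
            v = 0.5 * (value(ch[0]) + value(ch[1]))
        vals[id(node)] = v
        return v

    value(tree.seed_node)
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            total += abs(vals[id(node)] - vals[id(node.parent_node)])
    return total


def mk_matrix(q: float, t: float) -> np.ndarray:
    same = 0.5 + 0.5 * math.exp(-2.0 * q * t)
    return np.array([[same, 1 - same], [1 - same, same]])


def _joint_over_histories(phylo, states: dict, q: float):
    """Yield (assignment, probability) over all internal-state histories."""
    tree = phylo.dendropy_tree
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    for assign in itertools.product([0, 1], repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        prob = 0.5  # stationary root prior
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s_par = amap[id(node.parent_node)]
            s = states[node.taxon.label] if node.is_leaf() else amap[id(node)]
            prob *= mk_matrix(q, node.edge.length or 0.0)[s_par, s]
        yield amap, internals, prob


def mk_loglik_enumeration(phylo, states: dict, q: float) -> float:
    total = sum(p for _, _, p in _joint_over_histories(phylo, states, q))
    return math.log(total)


def mk_marginals_enumeration(phylo, states: dict, q: float) -> dict[frozenset, tuple]:
    """Marginal internal-node state probabilities keyed by tip set below."""
    accum: dict[int, np.ndarray] = {}
    internals_ref = None
    for amap, internals, prob in _joint_over_histories(phylo, states, q):
        internals_ref = internals
        for node in internals:
            arr = accum.setdefault(id(node), np.zeros(2))
            arr[amap[id(node)]] += prob
    out = {}
    for node in internals_ref:
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        p = accum[id(node)]
        p = p / p.sum()
        out[tips] = (float(p[0]), float(p[1]))
    return out


def pd_edge_union(phylo, assemblage, include_root: bool = True) -> float:
    """Faith's PD by explicit root-path edge-union enumeration."""
    tree = phylo.dendropy_tree
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    paths = []
    union: dict[int, float] = {}
    for sp in assemblage:
        node = leaves[sp]
        path = []
        while node is not None:
            path.append(node)
            union[id(node)] = float(node.edge.length or 0.0)
            node = node.parent_node
        paths.append(path)
    if not include_root:
        # drop the shared tail: every node present in all paths (the MRCA
        # and its ancestors, including the root)
        shared = set.intersection(*[set(id(n) for n in p) for p in paths])
        for nid in shared:
            union.pop(nid, None)
    return sum(union.values())


def equal_splits_apportionment(phylo) -> dict[str, float]:
    """Equal-splits rates by top-down apportionment of every edge.

    Each edge's length is handed down the tree, halving at every split;
    a tip's ES score is the total it receives, and its rate is 1/ES.
    """
    tree = phylo.dendropy_tree
    es: dict[str, float] = {l.taxon.label: 0.0 for l in tree.leaf_node_iter()}

    def distribute(node, amount: float) -> None:
        if node.is_leaf():
            es[node.taxon.label] += amount
            return
        for child in node.child_nodes():
            distribute(child, amount / len(node.child_nodes()))

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        distribute(node, float(node.edge.length or 0.0))
    return {sp: 1.0 / v for sp, v in es.items()}
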