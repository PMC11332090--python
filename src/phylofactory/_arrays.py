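"""Array-based tree kernels shared by the statistics modules.

A :class:`TreeArrays` is an immutable flat encoding of a
:class:`~phylofactory.treeio.Phylogeny` (preorder node indexing, parent
pointers, branch lengths) on which the hot loops run: sister-difference
sums, Brownian tip simulation, Faith's PD over many assemblages, and
patristic distance matrices.  All methods are vectorized across
replicate columns so permutation/bootstrap nulls cost one traversal.
"""

from __future__ import annotations

import numpy as np

from .treeio import Phylogeny

__all__ = ["TreeArrays"]


class TreeArrays:
    def __init__(self, phylo: Phylogeny):
        tree = phylo.dendropy_tree
        nodes = list(tree.preorder_node_iter())
        index = {id(node): i for i, node in enumerate(nodes)}
        m = len(nodes)
        self.n_nodes = m
        self.parent = np.full(m, -1, dtype=np.int64)
        self.blen = np.zeros(m, dtype=float)
        self.is_tip = np.zeros(m, dtype=bool)
        children: list[list[int]] = [[] for _ in range(m)]
        tip_nodes: list[int] = []
        tip_labels: list[str] = []
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p = index[id(node.parent_node)]
                self.parent[i] = p
                children[p].append(i)
                self.blen[i] = float(node.edge.length or 0.0)
            if node.is_leaf():
                self.is_tip[i] = True
                tip_nodes.append(i)
                tip_labels.append(node.taxon.label)
        self.children = children
        self.tip_nodes = np.asarray(tip_nodes, dtype=np.int64)
        self.tip_labels = list(tip_labels)
        self.n_tips = len(tip_labels)
        self.root_edge = float(tree.seed_node.edge.length or 0.0)
        # preorder == 0..m-1 by construction; postorder = reversed
        self.preorder = np.arange(m, dtype=np.int64)
        self.postorder = self.preorder[::-1]
        # node depths measured from the root node (stem excluded)
        self.depth = np.zeros(m, dtype=float)
        for i in range(1, m):
            self.depth[i] = self.depth[self.parent[i]] + self.blen[i]
        self.tip_depth = self.depth[self.tip_nodes]
        # rank of each tip when labels are sorted; deterministic tie-break
        order = np.argsort(np.asarray(self.tip_labels, dtype=object), kind="stable")
        self.tip_label_rank = np.empty(self.n_tips, dtype=np.int64)
        self.tip_label_rank[order] = np.arange(self.n_tips)
        self._tip_row = {lab: r for r, lab in enumerate(self.tip_labels)}

    # -- helpers -------------------------------------------------------

    def tip_rows(self, labels) -> np.ndarray:
        """Row indices (into tip-ordered arrays) for the given tip labels."""
        try:
            return np.asarray([self._tip_row[lab] for lab in labels], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"tip not in tree: {exc.args[0]!r}") from None

    @property
    def height(self) -> float:
        return float(self.tip_depth.max()) + self.root_edge

    # -- sister-difference sum (raw d of the clumping statistic) -------

    def sister_diff_sums(self, tip_values: np.ndarray) -> np.ndarray:
        """Sum over edges of |parent − child| nodal values.

        Internal nodal values are the unweighted mean of the two
        daughters (post-order averaging pass); requires a strictly
        bifurcating tree.  ``tip_values`` has shape (n_tips,) or
        (n_tips, k); a value per replicate column is returned.
        """
        vals1d = tip_values.ndim == 1
        tv = np.atleast_2d(tip_values.T).T.astype(float)  # (n_tips, k)
        k = tv.shape[1]
        vals = np.zeros((self.n_nodes, k), dtype=float)
        vals[self.tip_nodes] = tv
        for i in self.postorder:
            ch = self.children[i]
            if not ch:
                continue
            if len(ch) != 2:
                raise ValueError(
                    "sister-difference sum requires a bifurcating tree; "
                    "resolve polytomies first"
                )
            vals[i] = 0.5 * (vals[ch[0]] + vals[ch[1]])
        nonroot = self.preorder[1:]
        d = np.abs(vals[nonroot] - vals[self.parent[nonroot]]).sum(axis=0)
        return d[0] if vals1d else d

    # -- Brownian motion along branches --------------------------------

    def brownian_tip_values(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """k independent unit-rate Brownian realizations; shape (n_tips, k).

        Root value 0; each branch adds a Gaussian increment with
        variance equal to its length (the stem above the root adds
        nothing: thresholding is shift-invariant).
        """
        g = rng.standard_normal((self.n_nodes, k))
        vals = np.zeros((self.n_nodes, k), dtype=float)
        sd = np.sqrt(self.blen)
        for i in range(1, self.n_nodes):
            vals[i] = vals[self.parent[i]] + sd[i] * g[i]
        return vals[self.tip_nodes]

    def threshold_top_k(self, values: np.ndarray, prevalence: int) -> np.ndarray:
        """Binary states: 1 for the ``prevalence`` largest values per column.

        Ties (possible with zero-length branches) are broken by
        tip-label order, deterministically.
        """
        v = np.atleast_2d(values.T).T
        out = np.zeros_like(v, dtype=np.int8)
        for j in range(v.shape[1]):
            order = np.lexsort((self.tip_label_rank, -v[:, j]))
            out[order[:prevalence], j] = 1
        return out[:, 0] if values.ndim == 1 else out

    # -- Faith's PD over assemblages ------------------------------------

    def pd_values(self, indicators: np.ndarray, include_root: bool = True) -> np.ndarray:
        """Faith's PD for one or many assemblages.

        ``indicators``: boolean/0-1 array (n_tips,) or (n_tips, k).
        With ``include_root`` the union of root-to-tip paths is summed
        (root stem included when present); otherwise edges at or above
        the assemblage MRCA are dropped, leaving the minimal subtree
        connecting the tips alone.
        """
        ind1d = indicators.ndim == 1
        ind = np.atleast_2d(indicators.T).T.astype(np.int64)
        k = ind.shape[1]
        counts = np.zeros((self.n_nodes, k), dtype=np.int64)
        counts[self.tip_nodes] = ind
        for i in self.postorder:
            p = self.parent[i]
            if p >= 0:
                counts[p] += counts[i]
        richness = counts[0]  # root holds the assemblage size
        nonroot = self.preorder[1:]
        present = counts[nonroot] > 0
        if include_root:
            pd = self.blen[nonroot] @ present
            pd = pd + self.root_edge * (richness > 0)
        else:
            on_spine = counts[nonroot] == richness[None, :]
            pd = self.blen[nonroot] @ (present & ~on_spine)
        pd = np.asarray(pd, dtype=float)
        return pd[0] if ind1d else pd

    # -- patristic distances -------------------------------------------

    def patristic_matrix(self) -> np.ndarray:
        """Dense tip-by-tip patristic distance matrix (tip order rows)."""
        n = self.n_tips
        D = np.zeros((n, n), dtype=float)
        dep = np.zeros(self.n_nodes, dtype=float)
        dep[self.tip_nodes] = self.tip_depth
        tiplists: list[np.ndarray | None] = [None] * self.n_nodes
        rows = np.zeros(self.n_nodes, dtype=np.int64)
        rows[self.tip_nodes] = np.arange(n)
        for i in self.postorder:
            if self.is_tip[i]:
                tiplists[i] = np.array([rows[i]], dtype=np.int64)
                continue
            lists = [tiplists[c] for c in self.children[i]]
            for a_idx in range(len(lists)):
                for b_idx in range(a_idx + 1, len(lists)):
                    a, b = lists[a_idx], lists[b_idx]
                    block = (
                        self.tip_depth[a][:, None]
                        + self.tip_depth[b][None, :]
                        - 2.0 * self.depth[i]
                    )
                    D[np.ix_(a, b)] = block
                    D[np.ix_(b, a)] = block.T
            tiplists[i] = np.concatenate(lists)
        return D
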