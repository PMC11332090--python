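"""Reading, validating, pruning and interrogating rooted phylogenies.

Trees are held as rooted dendropy trees behind a thin :class:`Phylogeny`
facade that enforces the invariants every downstream statistic relies on:
a single root, unique non-empty tip labels, and non-negative branch
lengths.  Trees are treated as rooted exactly as written; no re-rooting
is ever performed.

Species names in companion tables frequently differ from tip labels only
in their space/underscore convention; :func:`normalize_label` is applied
symmetrically whenever names are matched against the tree.
"""

from __future__ import annotations

import logging
import random
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "Phylogeny",
    "NewickParseError",
    "TreeValidationError",
    "normalize_label",
    "parse_newick",
    "read_newick",
]

logger = logging.getLogger(__name__)


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


def normalize_label(label: str) -> str:
    """Canonical form used to match species names against tip labels.

    Spaces and underscores are interchangeable in practice (Newick
    writers quote spaces or swap them for underscores), so both map to a
    single underscore-separated form.
    """
    return "_".join(str(label).strip().split()).replace(" ", "_")


class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Wraps a :class:`dendropy.Tree`.  Polytomies are allowed; a strictly
    bifurcating view is available via :meth:`resolve_polytomies`.

    Parameters
    ----------
    tree:
        A rooted dendropy tree.  Ownership passes to the new object.
    default_branch_length:
        If ``None`` (default) a missing branch length on any non-root
        edge is a validation error; otherwise the constant substituted
        for missing lengths (substitutions are logged).
    """

    def __init__(self, tree: dendropy.Tree, default_branch_length: float | None = None):
        self._tree = tree
        self._validate(default_branch_length)

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, default_branch_length: float | None = None) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several DataError subclasses
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree, default_branch_length=default_branch_length)

    @classmethod
    def from_file(cls, path, default_branch_length: float | None = None) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read(), default_branch_length=default_branch_length)

    def _validate(self, default_branch_length: float | None) -> None:
        tree = self._tree
        if tree.seed_node is None:
            raise TreeValidationError("tree has no root")
        labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
        if any(lab is None or str(lab).strip() == "" for lab in labels):
            raise TreeValidationError("tree has an unlabeled or empty-labeled tip")
        seen: set[str] = set()
        dupes: set[str] = set()
        for lab in labels:
            if lab in seen:
                dupes.add(lab)
            seen.add(lab)
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        n_defaulted = 0
        for node in tree.preorder_node_iter():
            length = node.edge.length
            if node is tree.seed_node:
                # A root (stem) edge length is optional; pruning can
                # leave the stem of the retained subtree here.
                if length is not None and length < 0:
                    raise TreeValidationError("negative root edge length")
                continue
            if length is None:
                if default_branch_length is None:
                    raise TreeValidationError(
                        "missing branch length (pass default_branch_length to substitute)"
                    )
                node.edge.length = float(default_branch_length)
                n_defaulted += 1
            elif length < 0:
                raise TreeValidationError(f"negative branch length {length}")
        if n_defaulted:
            logger.warning("substituted default branch length on %d edges", n_defaulted)

    # -- basic queries -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in tree (preorder leaf) order."""
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def n_internal(self) -> int:
        return sum(1 for node in self._tree.preorder_node_iter() if not node.is_leaf())

    @property
    def root_edge_length(self) -> float:
        length = self._tree.seed_node.edge.length
        return float(length) if length is not None else 0.0

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths, including any root (stem) edge."""
        total = self.root_edge_length
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node and node.edge.length:
                total += node.edge.length
        return total

    @property
    def is_bifurcating(self) -> bool:
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) != 2:
                return False
        return True

    def tree_height(self) -> float:
        """Maximum root-to-tip path length (root stem included)."""
        return max(self.root_path_length(t) for t in self.tip_labels)

    def _tip_lookup(self) -> dict[str, dendropy.Node]:
        return {leaf.taxon.label: leaf for leaf in self._tree.leaf_node_iter()}

    def resolve_names(self, names: Iterable[str]) -> dict[str, str]:
        """Map external species names onto exact tip labels.

        Matching is first exact, then via :func:`normalize_label`.
        Returns ``{external name: tip label}``; raises ``KeyError``
        listing every name with no match.
        """
        labels = self.tip_labels
        exact = set(labels)
        normed = {}
        for lab in labels:
            normed.setdefault(normalize_label(lab), lab)
        out: dict[str, str] = {}
        missing: list[str] = []
        for name in names:
            if name in exact:
                out[name] = name
            elif normalize_label(name) in normed:
                out[name] = normed[normalize_label(name)]
            else:
                missing.append(name)
        if missing:
            raise KeyError(f"species not found in tree: {sorted(missing)}")
        return out

    # -- operations ----------------------------------------------------

    def root_path_length(self, tip: str) -> float:
        """Sum of branch lengths from ``tip`` to (and including any stem of) the root."""
        lookup = self._tip_lookup()
        if tip not in lookup:
            resolved = self.resolve_names([tip])  # raises KeyError if absent
            tip = resolved[tip]
            lookup = self._tip_lookup()
        node = lookup[tip]
        total = 0.0
        while node is not None:
            if node.edge.length:
                total += node.edge.length
            node = node.parent_node
        return total

    def prune_to_taxa(self, keep: Iterable[str]) -> "Phylogeny":
        """Prune to the given tip set.

        Degree-2 nodes created by pruning are suppressed with their
        branch lengths summed, so root-to-tip path lengths of retained
        tips are unchanged (the removed basal part of the tree survives
        as a stem length on the new root).
        """
        keep = list(dict.fromkeys(keep))
        if not keep:
            raise ValueError("empty keep set")
        mapping = self.resolve_names(keep)  # KeyError on unknown names
        labels = [mapping[k] for k in keep]
        ref_tip = labels[0]
        ref_depth = self.root_path_length(ref_tip)

        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(labels)
        pruned = Phylogeny(clone)
        # dendropy suppresses the pruned-away unifurcations; make the
        # depth-conservation contract explicit by absorbing any residual
        # discrepancy into the root stem.
        delta = ref_depth - pruned.root_path_length(ref_tip)
        if abs(delta) > 1e-9:
            stem = pruned.root_edge_length + delta
            if stem < -1e-9:
                raise TreeValidationError("pruning produced a negative stem length")
            clone.seed_node.edge.length = max(stem, 0.0)
        return pruned

    def resolve_polytomies(self, seed: int) -> "Phylogeny":
        """Return a strictly bifurcating copy.

        Polytomies are broken by inserting zero-length internal edges,
        so the tip set, total length and all patristic distances are
        unchanged.  Deterministic given ``seed``.
        """
        if self.is_bifurcating:
            return self
        clone = self._tree.clone(depth=1)
        clone.resolve_polytomies(rng=random.Random(int(seed)))
        for node in clone.preorder_node_iter():
            if node is not clone.seed_node and node.edge.length is None:
                node.edge.length = 0.0
        return Phylogeny(clone)

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny n_tips={self.n_tips} n_internal={self.n_internal}>"


def parse_newick(text: str, default_branch_length: float | None = None) -> Phylogeny:
    """Parse a single-tree Newick string into a validated :class:`Phylogeny`."""
    return Phylogeny.from_newick(text, default_branch_length=default_branch_length)


def read_newick(path, default_branch_length: float | None = None) -> Phylogeny:
    """Read a single-tree Newick file."""
    return Phylogeny.from_file(path, default_branch_length=default_branch_length)


def prune_to_taxa(tree: Phylogeny, keep: Sequence[str]) -> Phylogeny:
    return tree.prune_to_taxa(keep)


def resolve_polytomies(tree: Phylogeny, seed: int) -> Phylogeny:
    return tree.resolve_polytomies(seed)


def root_path_length(tree: Phylogeny, tip: str) -> float:
    return tree.root_path_length(tip)
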