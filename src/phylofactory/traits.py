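"""Binary trait vectors keyed by species name."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .treeio import Phylogeny

__all__ = ["TraitVector"]


@dataclass(frozen=True)
class TraitVector:
    """A species -> {0, 1} map, e.g. the naturalized or invasive flag.

    ``prevalence`` is the number of 1-states.  A trait is *analyzable*
    (for signal estimation) only when 0 < prevalence < n; boundary
    traits are representable but flagged by :meth:`is_invariant`.
    """

    states: Mapping[str, int]
    name: str = "trait"

    def __post_init__(self):
        bad = {k: v for k, v in self.states.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"non-binary trait values: {bad}")
        object.__setattr__(self, "states", dict(self.states))

    @classmethod
    def from_series(cls, series: pd.Series, name: str | None = None) -> "TraitVector":
        return cls({str(k): int(v) for k, v in series.items()}, name=name or str(series.name))

    @property
    def species(self) -> list[str]:
        return list(self.states)

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def prevalence(self) -> int:
        return int(sum(self.states.values()))

    def is_invariant(self) -> bool:
        return self.prevalence in (0, self.n)

    def __getitem__(self, species: str) -> int:
        return self.states[species]

    def aligned(self, tree_or_labels) -> np.ndarray:
        """0/1 array in tip order; every tip must be covered.

        Accepts a :class:`Phylogeny` or an explicit label sequence.
        Name matching tolerates the space/underscore convention.
        """
        if isinstance(tree_or_labels, Phylogeny):
            mapping = tree_or_labels.resolve_names(self.species)
            by_tip = {mapping[sp]: v for sp, v in self.states.items()}
            labels = tree_or_labels.tip_labels
        else:
            by_tip = dict(self.states)
            labels = list(tree_or_labels)
        missing = [lab for lab in labels if lab not in by_tip]
        if missing:
            raise KeyError(f"trait '{self.name}' missing species: {sorted(missing)[:10]}")
        return np.asarray([by_tip[lab] for lab in labels], dtype=np.int8)

    def restricted_to(self, species) -> "TraitVector":
        keep = set(species)
        return TraitVector({k: v for k, v in self.states.items() if k in keep}, name=self.name)
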