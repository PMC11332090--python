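"""Readers and writers for the pipeline's tabular formats.

All tables are plain CSV; lines starting with ``#`` are comments (the
pipeline writes provenance headers that way).  Schemas:

* status:       ``species,naturalized,invasive`` (flags 0/1)
* occurrences:  ``species,realm,biome`` — one row per record
* clades:       ``species,clade``
* areas:        ``region,area_km2``
* rates:        ``species,rate`` (see :mod:`phylofactory.divreg`)
"""

from __future__ import annotations

import pandas as pd

from .traits import TraitVector

__all__ = [
    "read_status_table",
    "read_occurrences",
    "read_clades",
    "read_areas",
    "trait_from_status",
]


def _read(path, required: set[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if not required.issubset(df.columns):
        raise ValueError(
            f"{what} table needs columns {sorted(required)}; got {list(df.columns)}"
        )
    return df


def read_status_table(path) -> pd.DataFrame:
    df = _read(path, {"species", "naturalized", "invasive"}, "status")
    df["species"] = df["species"].astype(str)
    dupes = df["species"][df["species"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate species in status table: {sorted(dupes)[:5]}")
    for col in ("naturalized", "invasive"):
        vals = set(df[col].unique())
        if not vals <= {0, 1}:
            raise ValueError(f"status column {col!r} must be 0/1; got {sorted(vals)[:5]}")
    return df


def trait_from_status(status: pd.DataFrame, trait: str) -> TraitVector:
    if trait not in ("naturalized", "invasive"):
        raise ValueError("trait must be 'naturalized' or 'invasive'")
    return TraitVector.from_series(status.set_index("species")[trait], name=trait)


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "species" not in df.columns or not ({"realm", "biome"} & set(df.columns)):
        raise ValueError(
            f"occurrence table needs 'species' and 'realm'/'biome' columns; got {list(df.columns)}"
        )
    df["species"] = df["species"].astype(str)
    return df


def read_clades(path) -> pd.DataFrame:
    df = _read(path, {"species", "clade"}, "clades")
    df["species"] = df["species"].astype(str)
    return df


def read_areas(path) -> pd.DataFrame:
    df = _read(path, {"region", "area_km2"}, "areas")
    return df
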