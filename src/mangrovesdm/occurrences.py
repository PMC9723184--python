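"""Occurrence records: multi-source merging and spatial rarefaction.

Occurrence data mix archival records (databases, literature) with
GPS-verified field records. Before modelling they are merged, exact
duplicates collapsed, and spatially rarefied to at most one record per
species per 1-km grid cell to limit spatial sampling bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridDefinition, GridMismatchError
from .species import validate_codes

COLUMNS = ("species_code", "x", "y", "source", "cell_id")
SOURCES = ("archive", "field")


class OccurrenceSet:
    """Per-species presence points on one analysis grid.

    Wraps a DataFrame with columns species_code, x, y, source, cell_id.
    Coordinates are planar; cell assignment follows the grid's half-open
    cell membership. ``validate_registry=False`` admits codes outside the
    packaged 18-species registry (user-extended registries).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        grid: GridDefinition,
        validate_registry: bool = True,
        crs_note: str = "planar grid coordinates, km",
    ):
        df = records.copy().reset_index(drop=True)
        missing = [c for c in ("species_code", "x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"occurrence table missing column(s): {missing}")
        if "source" not in df.columns:
            df["source"] = "field"
        bad_src = set(df["source"]) - set(SOURCES)
        if bad_src:
            raise ValueError(f"unknown source tag(s): {sorted(bad_src)}")
        if len(df):
            df["cell_id"] = grid.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
        else:
            df["cell_id"] = pd.Series([], dtype=int)
        if validate_registry and len(df):
            validate_codes(df["species_code"].unique())
        self.records = df[list(COLUMNS)]
        self.grid = grid
        self.crs_note = crs_note

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species_code"].unique())

    def for_species(self, code: str) -> pd.DataFrame:
        return self.records[self.records["species_code"] == code]

    def cells_for_species(self, code: str) -> np.ndarray:
        return self.for_species(code)["cell_id"].to_numpy()

    def counts_by_species(self) -> pd.Series:
        return self.records["species_code"].value_counts().sort_index()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: GridDefinition, **kw) -> "OccurrenceSet":
        return cls(pd.read_csv(path), grid, **kw)


def merge_sources(archive: OccurrenceSet, field: OccurrenceSet) -> OccurrenceSet:
    """Union of archive and field records with source tags preserved.

    Exact coordinate duplicates (same species, same x, y) are collapsed to
    one record, keeping the field-source copy (field records are
    GPS-verified and take precedence).
    """
    if not archive.grid.same_geometry(field.grid):
        raise GridMismatchError("archive and field sets are on different grids")
    frames = [s.records for s in (archive, field) if len(s)]
    if not frames:
        return OccurrenceSet(archive.records, archive.grid, validate_registry=False)
    merged = pd.concat(frames, ignore_index=True)
    # field last wins under keep="last" after a stable sort putting field after archive
    merged["_src_rank"] = (merged["source"] == "field").astype(int)
    merged = merged.sort_values("_src_rank", kind="stable")
    merged = merged.drop_duplicates(subset=["species_code", "x", "y"], keep="last")
    merged = merged.drop(columns="_src_rank").reset_index(drop=True)
    return OccurrenceSet(merged, archive.grid, validate_registry=False)


def rarefy_to_grid(occ: OccurrenceSet, grid: GridDefinition | None = None, seed: int = 0) -> OccurrenceSet:
    """Keep exactly one record per (species, cell).

    Field-source records are preferred over archival ones when a cell holds
    both; ties are broken uniformly at random under the seed. Idempotent:
    rarefying an already-rarefied set returns it unchanged (up to row
    order, which is normalised by sorting).
    """
    grid = grid or occ.grid
    if not grid.same_geometry(occ.grid):
        raise GridMismatchError("rarefaction grid differs from the occurrence grid")
    df = occ.records.copy()
    rng = np.random.default_rng(seed)
    df["_u"] = rng.random(len(df))
    df["_pref"] = (df["source"] == "field").astype(int)
    df = df.sort_values(["species_code", "cell_id", "_pref", "_u"], ascending=[True, True, False, True], kind="stable")
    kept = df.groupby(["species_code", "cell_id"], as_index=False, sort=True).head(1)
    kept = kept.drop(columns=["_u", "_pref"]).sort_values(["species_code", "cell_id"]).reset_index(drop=True)
    return OccurrenceSet(kept, grid, validate_registry=False)
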