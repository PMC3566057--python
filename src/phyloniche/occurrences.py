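"""Georeferenced occurrence points.

Occurrences are "spatially unique": after snapping to grid cells, at most one
point per species per cell is kept. Modeling operates on cells, so duplicate
records within a cell carry no extra information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .rasters import GridSpec

__all__ = ["OccurrenceSet", "read_occurrences", "write_occurrences"]

MIN_POINTS = 10  # minimum spatially unique points required to model a species


@dataclass
class OccurrenceSet:
    """Occurrence localities of one species, lon/lat degrees."""

    species: str
    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not str(self.species):
            raise ValueError("empty species label")
        self.points = [(float(x), float(y)) for x, y in self.points]

    def __len__(self) -> int:
        return len(self.points)

    def cells(self, spec: GridSpec) -> list[tuple[int, int]]:
        """Grid cells of the points (row, col), in point order."""
        return [spec.cell_of(x, y) for x, y in self.points]

    def snapped(self, spec: GridSpec) -> "OccurrenceSet":
        """Deduplicate at cell resolution; points move to cell centers."""
        seen: dict[tuple[int, int], None] = {}
        for x, y in self.points:
            seen.setdefault(spec.cell_of(x, y), None)
        return OccurrenceSet(
            self.species, [spec.cell_center(r, c) for r, c in seen]
        )


def read_occurrences(path: str | Path, grid_spec: GridSpec) -> list[OccurrenceSet]:
    """Read a species,lon,lat CSV and snap to the grid.

    Points are deduplicated per species at grid-cell resolution. Any point
    outside the grid extent is an error listing the offending CSV rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: CSV must have columns species,lon,lat")
    if df["species"].isna().any() or (df["species"].astype(str) == "").any():
        raise ValueError(f"{path}: empty species label")
    bad_rows = []
    for i, row in df.iterrows():
        if not grid_spec.contains(float(row["lon"]), float(row["lat"])):
            bad_rows.append(i + 2)  # 1-based with header line
    if bad_rows:
        raise ValueError(f"{path}: points outside grid extent at CSV lines {bad_rows}")
    out = []
    for species, grp in df.groupby("species", sort=True):
        pts = list(zip(grp["lon"].astype(float), grp["lat"].astype(float)))
        out.append(OccurrenceSet(str(species), pts).snapped(grid_spec))
    return out


def write_occurrences(sets: list[OccurrenceSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species,lon,lat\n")
        for occ in sets:
            for x, y in occ.points:
                fh.write(f"{occ.species},{x!r},{y!r}\n")
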