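"""ESRI ASCII grid rasters and grid geometry.

All rasters in the pipeline live on a single lon/lat grid (WGS84 degrees
assumed, no projection support). Values are stored north-to-south: row 0 of
the value array is the northernmost row, matching the ASCII-grid convention.
Cells equal to the grid's nodata sentinel are "invalid" and excluded from all
downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "Raster",
    "RasterStack",
    "FormatError",
    "read_ascii_grid",
    "write_ascii_grid",
]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    ``x_ll``/``y_ll`` locate the lower-left corner of the lower-left (south-
    western) cell. Two specs are co-registered iff all five geometry fields
    and the nodata sentinel are equal.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    x_ll: float
    y_ll: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def x_max(self) -> float:
        return self.x_ll + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_ll + self.n_rows * self.cell_size

    def contains(self, x: float, y: float) -> bool:
        """Half-open containment: [x_ll, x_max) x [y_ll, y_max)."""
        return self.x_ll <= x < self.x_max and self.y_ll <= y < self.y_max

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing (x, y), row 0 at the north.

        Uses the half-open convention [left, right) / [bottom, top) so that
        snapping is deterministic on cell boundaries.
        """
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        col = int(np.floor((x - self.x_ll) / self.cell_size))
        row_s = int(np.floor((y - self.y_ll) / self.cell_size))
        return self.n_rows - 1 - row_s, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Lon/lat of the center of cell (row, col), row 0 at the north."""
        x = self.x_ll + (col + 0.5) * self.cell_size
        y = self.y_ll + (self.n_rows - 1 - row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of cell-center lon and lat."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_ll + (cols + 0.5) * self.cell_size
        y = self.y_ll + (self.n_rows - 1 - rows + 0.5) * self.cell_size
        return np.broadcast_to(x, (self.n_rows, self.n_cols)).copy(), np.broadcast_to(
            y[:, None], (self.n_rows, self.n_cols)
        ).copy()


@dataclass
class Raster:
    """One climate variable on a grid; row 0 is the northernmost row."""

    spec: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )
        ok = np.isfinite(self.values) | (self.values == self.spec.nodata)
        if not ok.all():
            raise ValueError("raster contains non-finite values that are not nodata")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values) & (self.values != self.spec.nodata)


class RasterStack:
    """Ordered collection of co-registered rasters (the climate layers).

    A cell is valid in the stack iff it is valid in every layer.
    """

    def __init__(self, layers: Sequence[Raster]):
        layers = list(layers)
        if not layers:
            raise ValueError("stack needs at least one layer")
        spec = layers[0].spec
        for lay in layers[1:]:
            if lay.spec != spec:
                raise ValueError(
                    f"layer {lay.name!r} is not co-registered with {layers[0].name!r}"
                )
        names = [lay.name for lay in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.layers = layers
        self.spec = spec

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self) -> Iterator[Raster]:
        return iter(self.layers)

    def __getitem__(self, name: str) -> Raster:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [lay.name for lay in self.layers]

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones((self.spec.n_rows, self.spec.n_cols), dtype=bool)
        for lay in self.layers:
            mask &= lay.valid_mask
        return mask

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])


# -- ASCII grid I/O ---------------------------------------------------------

def _fmt(x: float) -> str:
    """Shortest exact decimal for a float; integers without trailing '.0'."""
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def read_ascii_grid(path: str | Path, name: str | None = None) -> Raster:
    """Read an ESRI ASCII grid (.asc).

    The six header lines NCOLS/NROWS/XLLCORNER/YLLCORNER/CELLSIZE/NODATA_VALUE
    (case-insensitive) are followed by n_rows*n_cols whitespace-separated
    numbers, first row northernmost. Malformed input raises :class:`FormatError`
    naming the offending line; nothing is silently repaired.
    """
    path = Path(path)
    text = path.read_text().split("\n")
    header: dict[str, float] = {}
    i = 0
    while i < len(text) and len(header) < 6:
        line = text[i].strip()
        i += 1
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: line {i}: expected 'KEY value' header, got {line!r}")
        key = parts[0].lower()
        if key != _HEADER_KEYS[len(header)]:
            raise FormatError(
                f"{path}: line {i}: expected header token "
                f"{_HEADER_KEYS[len(header)].upper()}, got {parts[0]!r}"
            )
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: bad number {parts[1]!r}") from exc
    if len(header) < 6:
        raise FormatError(f"{path}: truncated header ({len(header)}/6 tokens)")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    if n_cols != header["ncols"] or n_rows != header["nrows"]:
        raise FormatError(f"{path}: NCOLS/NROWS must be integers")
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        nodata=header["nodata_value"],
    )
    tokens = "\n".join(text[i:]).split()
    expected = n_rows * n_cols
    if len(tokens) != expected:
        raise FormatError(
            f"{path}: expected {expected} data values after line {i}, found {len(tokens)}"
        )
    try:
        values = np.array(tokens, dtype=float).reshape(n_rows, n_cols)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data value after line {i}") from exc
    return Raster(spec=spec, values=values, name=name if name is not None else path.stem)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid; round-trips through
    :func:`read_ascii_grid` with identical header and values."""
    path = Path(path)
    spec = raster.spec
    lines = [
        f"NCOLS {spec.n_cols}",
        f"NROWS {spec.n_rows}",
        f"XLLCORNER {_fmt(spec.x_ll)}",
        f"YLLCORNER {_fmt(spec.y_ll)}",
        f"CELLSIZE {_fmt(spec.cell_size)}",
        f"NODATA_VALUE {_fmt(spec.nodata)}",
    ]
    for row in raster.values:
        lines.append(" ".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
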