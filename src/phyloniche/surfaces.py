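"""RAW suitability surfaces.

A suitability surface is a probability distribution over the valid cells of
the study grid: nonnegative weights summing to one ("RAW" output convention
of presence-background models). It is the common currency consumed by the
overlap statistics and the predicted-niche-occupancy profiles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .rasters import GridSpec, Raster, read_ascii_grid, write_ascii_grid

__all__ = ["SuitabilitySurface"]

_SUM_TOL = 1e-9


class SuitabilitySurface:
    """Unit-mass nonnegative weights per valid grid cell.

    ``weights`` is an (n_rows, n_cols) array with zeros on invalid cells;
    ``valid_mask`` marks the cells over which the distribution is defined.
    """

    def __init__(
        self,
        spec: GridSpec,
        weights: np.ndarray,
        valid_mask: np.ndarray,
        species: str = "",
    ):
        weights = np.asarray(weights, dtype=float)
        valid_mask = np.asarray(valid_mask, dtype=bool)
        if weights.shape != (spec.n_rows, spec.n_cols) or valid_mask.shape != weights.shape:
            raise ValueError("weights/valid_mask shape does not match grid")
        if (weights < 0).any() or not np.isfinite(weights).all():
            raise ValueError("weights must be finite and nonnegative")
        if weights[~valid_mask].any():
            raise ValueError("nonzero weight on invalid cell")
        total = weights.sum()
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"weights sum to {total!r}, expected 1 within {_SUM_TOL}")
        self.spec = spec
        self.weights = weights
        self.valid_mask = valid_mask
        self.species = str(species)

    @classmethod
    def from_unnormalized(
        cls,
        spec: GridSpec,
        raw: np.ndarray,
        valid_mask: np.ndarray,
        species: str = "",
    ) -> "SuitabilitySurface":
        raw = np.where(valid_mask, np.asarray(raw, dtype=float), 0.0)
        total = raw.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("cannot normalize: total suitability is not positive")
        return cls(spec, raw / total, valid_mask, species=species)

    def co_registered_with(self, other: "SuitabilitySurface") -> bool:
        return self.spec == other.spec

    # -- I/O ----------------------------------------------------------------
    def to_raster(self, name: str | None = None) -> Raster:
        values = np.where(self.valid_mask, self.weights, self.spec.nodata)
        return Raster(self.spec, values, name=name or self.species)

    def write_asc(self, path: str | Path) -> None:
        write_ascii_grid(self.to_raster(), path)

    @classmethod
    def read_asc(cls, path: str | Path, species: str | None = None) -> "SuitabilitySurface":
        raster = read_ascii_grid(path)
        mask = raster.valid_mask
        return cls.from_unnormalized(
            raster.spec, raster.values, mask, species=species or raster.name
        )
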