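"""Predicted niche occupancy (PNO) profiles.

A PNO profile integrates a species' RAW suitability surface over the values
of one climate variable: the variable's study-wide range is divided into
equally spaced bins (50 by default) and each bin receives the suitability
mass of the cells whose variable value falls in it. The result is a unit-mass
histogram — the species' climatic-tolerance profile for that variable.

Bin ranges are shared by all species (global min/max of the variable over
the valid study area) so that profiles, reconstructions and disparity
analyses are comparable on one axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .rasters import Raster
from .surfaces import SuitabilitySurface

__all__ = [
    "PNOProfile",
    "compute_pno",
    "pno_weighted_mean",
    "sample_pno",
    "gaussian_profile",
]

DEFAULT_BINS = 50
_SUM_TOL = 1e-9


@dataclass
class PNOProfile:
    """Unit-mass histogram of suitability over one variable's range."""

    variable: str
    edges: np.ndarray  # n_bins + 1 equally spaced edges, variable units
    masses: np.ndarray  # n_bins nonnegative masses summing to 1
    species: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.edges.size != self.masses.size + 1:
            raise ValueError("edges must have one more entry than masses")
        if self.masses.size < 2:
            raise ValueError("need at least 2 bins")
        widths = np.diff(self.edges)
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=0):
            raise ValueError("bins must be equally spaced")
        if widths[0] <= 0:
            raise ValueError("bin edges must be increasing")
        if (self.masses < 0).any():
            raise ValueError("negative bin mass")
        if abs(self.masses.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"masses sum to {self.masses.sum()!r}, expected 1")

    @property
    def n_bins(self) -> int:
        return self.masses.size

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def compute_pno(
    surface: SuitabilitySurface,
    variable_raster: Raster,
    n_bins: int = DEFAULT_BINS,
    bin_range: tuple[float, float] | None = None,
) -> PNOProfile:
    """Bin a species' suitability mass by the values of one climate variable.

    ``bin_range`` defaults to the variable's min/max over its valid study
    cells (global, shared across species). A cell's mass goes to the bin
    whose half-open interval [edge_b, edge_{b+1}) contains its value; the
    last bin is closed. Mass is renormalized to 1 (a no-op unless
    ``bin_range`` clips part of the surface).
    """
    if surface.spec != variable_raster.spec:
        raise ValueError("surface and variable raster are not co-registered")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    var_valid = variable_raster.valid_mask
    if bin_range is None:
        vals = variable_raster.values[var_valid]
        if vals.size == 0:
            raise ValueError("variable raster has no valid cells")
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = map(float, bin_range)
    if hi <= lo:
        raise ValueError(
            f"variable {variable_raster.name!r} has zero range ({lo}); cannot bin"
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    mask = surface.valid_mask & var_valid
    x = variable_raster.values[mask]
    w = surface.weights[mask]
    width = (hi - lo) / n_bins
    idx = np.floor((x - lo) / width).astype(int)
    idx = np.where(x == hi, n_bins - 1, idx)  # last bin closed
    keep = (idx >= 0) & (idx < n_bins)
    masses = np.bincount(idx[keep], weights=w[keep], minlength=n_bins)
    total = masses.sum()
    if total <= 0:
        raise ValueError("no suitability mass falls inside the bin range")
    return PNOProfile(
        variable=variable_raster.name,
        edges=edges,
        masses=masses / total,
        species=surface.species,
    )


def pno_weighted_mean(profile: PNOProfile) -> float:
    """Suitability-weighted mean of the variable: sum of midpoint * mass."""
    return float(profile.midpoints @ profile.masses)


def sample_pno(
    profile: PNOProfile,
    n_draws: int = 100,
    seed: int | np.random.Generator = 0,
    jitter: bool = False,
) -> np.ndarray:
    """Draw values from the profile: bin midpoints with probability equal to
    bin mass, with replacement. ``jitter=True`` instead places each draw
    uniformly within its bin."""
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = rng.choice(profile.n_bins, size=n_draws, p=profile.masses)
    if jitter:
        width = profile.edges[1] - profile.edges[0]
        return profile.edges[bins] + rng.uniform(0.0, width, size=n_draws)
    return profile.midpoints[bins]


def gaussian_profile(
    variable: str,
    center: float,
    width: float,
    bin_range: tuple[float, float],
    n_bins: int = DEFAULT_BINS,
    species: str = "",
) -> PNOProfile:
    """Profile of a parametric Gaussian tolerance curve.

    Bins the normal density N(center, width^2) over ``bin_range`` and
    renormalizes — the profile a species with a clean Gaussian response
    would have if its suitability were integrated over a variable uniformly
    covering the range.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    lo, hi = map(float, bin_range)
    edges = np.linspace(lo, hi, n_bins + 1)
    cdf = norm.cdf(edges, loc=center, scale=width)
    masses = np.diff(cdf)
    total = masses.sum()
    if total <= 0:
        raise ValueError("tolerance curve has no mass inside the bin range")
    return PNOProfile(variable=variable, edges=edges, masses=masses / total, species=species)


def profiles_to_csv(profiles: list[PNOProfile], path: str | Path) -> None:
    """Long-format CSV: variable, species, bin_mid, mass."""
    rows = []
    for p in profiles:
        for mid, mass in zip(p.midpoints, p.masses):
            rows.append((p.variable, p.species, mid, mass))
    pd.DataFrame(rows, columns=["variable", "species", "bin_mid", "mass"]).to_csv(
        path, index=False
    )
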