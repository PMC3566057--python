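"""Niche overlap between RAW suitability surfaces.

Schoener's D and the Hellinger-derived I compare two unit-mass suitability
distributions over the study cells:

    D(p, q) = 1 - 1/2 * sum_i |p_i - q_i|
    I(p, q) = 1 - 1/2 * sum_i (sqrt(p_i) - sqrt(q_i))^2

Both range from 0 (no overlap of suitability mass) to 1 (identical
distributions). Cells invalid in either surface are excluded from both sums
and each surface is renormalized over the common valid set, preserving the
unit-mass premise.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import CladeMap
from .surfaces import SuitabilitySurface

__all__ = ["schoener_D", "hellinger_I", "overlap_matrix", "OverlapMatrix"]


def _common(pX: SuitabilitySurface, pY: SuitabilitySurface):
    if pX.spec != pY.spec:
        raise ValueError("surfaces are not co-registered")
    mask = pX.valid_mask & pY.valid_mask
    p = pX.weights[mask]
    q = pY.weights[mask]
    sp, sq = p.sum(), q.sum()
    if sp <= 0 or sq <= 0:
        raise ValueError("no overlapping valid mass to compare")
    return p / sp, q / sq


def schoener_D(pX: SuitabilitySurface, pY: SuitabilitySurface) -> float:
    """Schoener's D in [0, 1]; symmetric; 1 iff the surfaces coincide."""
    p, q = _common(pX, pY)
    return float(np.clip(1.0 - 0.5 * np.abs(p - q).sum(), 0.0, 1.0))


def hellinger_I(pX: SuitabilitySurface, pY: SuitabilitySurface) -> float:
    """Warren et al.'s I = 1 - H^2/2 with H the Hellinger distance."""
    p, q = _common(pX, pY)
    h2 = float(((np.sqrt(p) - np.sqrt(q)) ** 2).sum())
    return float(np.clip(1.0 - 0.5 * h2, 0.0, 1.0))


class OverlapMatrix:
    """Pairwise overlap table: D above the diagonal, I below, 1 on it."""

    def __init__(
        self,
        species: list[str],
        matrix: np.ndarray,
        clade_map: CladeMap | None = None,
    ):
        self.species = list(species)
        self.matrix = np.asarray(matrix, dtype=float)
        self.clade_map = clade_map

    def D(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        if i == j:
            return 1.0
        return float(self.matrix[min(i, j), max(i, j)])

    def I(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        if i == j:
            return 1.0
        return float(self.matrix[max(i, j), min(i, j)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    def write_csv(self, path: str | Path) -> None:
        """Two-decimal matrix CSV plus clade and shading-band annotations.

        The style column mirrors the published figure's legend: values in
        (0.50, 1] are 'dark', [0.11, 0.50] 'light', below 'none'; it applies
        to each row's off-diagonal mean as a reading aid.
        """
        df = self.to_dataframe().round(2)
        if self.clade_map is not None:
            df.insert(0, "clade", [self.clade_map.assignments.get(s, "") for s in self.species])
        n = len(self.species)
        off = self.matrix[~np.eye(n, dtype=bool)].reshape(n, n - 1) if n > 1 else np.ones((n, 0))
        style = []
        for row in off:
            m = row.mean() if row.size else 1.0
            style.append("dark" if m > 0.50 else ("light" if m >= 0.11 else "none"))
        df["style"] = style
        df.to_csv(path, float_format="%.2f")


def overlap_matrix(
    surfaces: list[SuitabilitySurface], clade_map: CladeMap | None = None
) -> OverlapMatrix:
    """Assemble the D (above diagonal) / I (below diagonal) matrix."""
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces")
    labels = [s.species for s in surfaces]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels among surfaces")
    n = len(surfaces)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = schoener_D(surfaces[i], surfaces[j])
            mat[j, i] = hellinger_I(surfaces[i], surfaces[j])
    return OverlapMatrix(labels, mat, clade_map=clade_map)
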