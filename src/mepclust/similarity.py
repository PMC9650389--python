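"""Hodgkin similarity indices and electrostatic distances over pair masks.

For two potentials phi_a, phi_b sampled at the same lattice points k of
a comparison mask, the Hodgkin similarity index is

    SI = 2 sum_k phi_a(k) phi_b(k) / (sum_k phi_a(k)^2 + sum_k phi_b(k)^2)

with SI = 1 for identical fields and SI = -1 for sign-flipped ones, and
the electrostatic distance is D = sqrt(2 - 2 SI) in [0, 2].  Each pair
(i, j) is compared on its own mask, the intersection of both skins with
the focus cylinder; consequently the SI matrix need not be positive
semi-definite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedSimilarityError
from .electrostatics import PotentialGrid
from .regions import RegionMask, pair_mask

_CLAMP_TOL = 1e-9


def hodgkin_index(a: PotentialGrid, b: PotentialGrid, mask: RegionMask) -> float:
    """Hodgkin SI of two congruent grids over a mask (>=1 point)."""
    if a.spec != b.spec or a.spec != mask.spec:
        raise DataError("grids and mask must share one grid spec")
    if mask.count < 1:
        raise DataError("comparison mask is empty")
    va = a.values[mask.included]
    vb = b.values[mask.included]
    denom = float(va @ va + vb @ vb)
    if denom == 0:
        raise UndefinedSimilarityError(
            f"both grids ({a.label!r}, {b.label!r}) are zero on the comparison mask"
        )
    si = 2.0 * float(va @ vb) / denom
    return float(np.clip(si, -1.0, 1.0))


def si_to_distance(si: float) -> float:
    """Electrostatic distance D = sqrt(2 - 2 SI); strictly decreasing in SI."""
    if si > 1 + _CLAMP_TOL or si < -1 - _CLAMP_TOL:
        raise ValueError(f"SI = {si} outside [-1, 1]")
    si = float(np.clip(si, -1.0, 1.0))
    return float(np.sqrt(2.0 - 2.0 * si))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric SI and D tables plus per-pair mask point counts."""

    labels: tuple[str, ...]
    si: np.ndarray
    d: np.ndarray
    points_used: np.ndarray

    def si_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.si, index=list(self.labels), columns=list(self.labels))

    def d_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points_used, index=list(self.labels), columns=list(self.labels)
        )

    def write_tsv(self, si_path: str | Path, d_path: str | Path, points_path: str | Path) -> None:
        self.si_frame().to_csv(si_path, sep="\t", float_format="%.12g")
        self.d_frame().to_csv(d_path, sep="\t", float_format="%.12g")
        self.points_frame().to_csv(points_path, sep="\t")


def similarity_matrix(
    grids: list[PotentialGrid],
    skins: list[RegionMask],
    cylinder: RegionMask,
) -> SimilarityMatrix:
    """All-pairs Hodgkin SI with pair-specific masks (skin_i ^ skin_j ^ cyl).

    Requires at least 3 grids (the pipeline's minimum-input rule) on one
    shared grid spec.  Diagonal entries are fixed to SI = 1, D = 0 by
    definition.
    """
    n = len(grids)
    if n < 3:
        raise DataError(f"at least 3 complexes are required, got {n}")
    if len(skins) != n:
        raise DataError("one skin mask per grid is required")
    labels = tuple(g.label for g in grids)
    if len(set(labels)) != n:
        raise DataError("complex labels must be unique")
    si = np.eye(n)
    points = np.zeros((n, n), dtype=int)
    for i in range(n):
        points[i, i] = pair_mask(
            skins[i], skins[i], cylinder, labels=(labels[i], labels[i])
        ).count
    for i in range(n):
        for j in range(i + 1, n):
            mask = pair_mask(skins[i], skins[j], cylinder, labels=(labels[i], labels[j]))
            val = hodgkin_index(grids[i], grids[j], mask)
            si[i, j] = si[j, i] = val
            points[i, j] = points[j, i] = mask.count
    d = np.sqrt(np.clip(2.0 - 2.0 * si, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return SimilarityMatrix(labels=labels, si=si, d=d, points_used=points)
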