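"""Molecular electrostatic potential grids and the analytic prescreen.

The potential model is a screened Coulomb (Debye-Hueckel) sum in a
uniform dielectric,

    phi(r) = (C / eps) * sum_i q_i * exp(-kappa d_i) / d_i,
    d_i = max(|r - r_i|, floor),

with C = 332.0637 kcal mol^-1 A e^-2 so that phi is in
kcal mol^-1 e^-1 when charges are in elementary charges and distances in
Angstrom.  kappa is the inverse Debye length derived from the ionic
strength and temperature; kappa = 0 recovers plain Coulomb.  This is a
deliberate simplification relative to a finite-difference
Poisson-Boltzmann solver: the downstream comparison statistic is
evaluated on a solvent shell away from the molecular surface, where the
field shape is dominated by the geometry of the net charges, and the
module boundary lets a PB solver be slotted in behind the same
:class:`PotentialGrid` contract.

A fast analytic prescreen compares truncated multipole (monopole +
dipole) fields on a spherical point shell; it is advisory output only —
final clustering always uses the grid-based similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as sc

from .errors import DataError
from .structure import Structure

#: Coulomb constant, kcal mol^-1 Angstrom e^-2
COULOMB_CONSTANT = 332.0637


@dataclass(frozen=True)
class GridSpec:
    """A regular axis-aligned lattice shared by all complexes in a run."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin, dtype=float)
        return tuple(o[i] + self.spacing * np.arange(self.dims[i]) for i in range(3))

    def points(self) -> np.ndarray:
        """All lattice points as an (N, 3) array in C (x-major) order."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class PotentialGrid:
    """Potential phi on a lattice, kcal mol^-1 e^-1."""

    spec: GridSpec
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != self.spec.shape:
            raise ValueError("values shape does not match grid spec dims")
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"non-finite potential values in grid {self.label!r}")


@dataclass(frozen=True)
class ElectrostaticsParams:
    """Solvent/solver parameters for the screened-Coulomb model."""

    epsilon: float = 78.4  # relative dielectric
    ionic_strength: float = 0.05  # mol/L, 1:1 electrolyte
    temperature: float = 298.15  # K
    coulomb_constant: float = COULOMB_CONSTANT
    singularity_floor: float = 0.5  # Angstrom

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kappa(self) -> float:
        """Inverse Debye length, 1/Angstrom (0 at zero ionic strength)."""
        if self.ionic_strength == 0:
            return 0.0
        # kappa^2 = 2 e^2 N_A (1000 I) / (eps0 eps_r kB T), SI
        kappa_sq = (
            2
            * sc.elementary_charge**2
            * sc.Avogadro
            * (1000.0 * self.ionic_strength)
            / (sc.epsilon_0 * self.epsilon * sc.Boltzmann * self.temperature)
        )
        return float(np.sqrt(kappa_sq) * 1e-10)


@dataclass(frozen=True)
class MultipoleSummary:
    """Net charge and dipole of a structure about its charge centroid."""

    net_charge: float  # e
    dipole: tuple[float, float, float]  # e Angstrom
    center: tuple[float, float, float]  # Angstrom


def build_grid_spec(cylinder, spacing: float = 1.0, padding: float = 5.0) -> GridSpec:
    """Axis-aligned lattice containing ``cylinder`` dilated by ``padding``.

    The bounding box of an arbitrarily oriented cylinder with unit axis
    ``a``, half-length h and radius r has per-coordinate half-extent
    ``h |a_k| + r sqrt(1 - a_k^2)``.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be > 0")
    center = np.asarray(cylinder.center, dtype=float)
    axis = np.asarray(cylinder.axis, dtype=float)
    half = 0.5 * cylinder.length * np.abs(axis) + cylinder.radius * np.sqrt(
        np.clip(1.0 - axis**2, 0.0, 1.0)
    )
    lo = center - half - padding
    hi = center + half + padding
    dims = tuple(int(np.floor((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return GridSpec(origin=tuple(lo), spacing=spacing, dims=dims)


def compute_potential_grid(
    structure: Structure,
    spec: GridSpec,
    params: ElectrostaticsParams | None = None,
    chunk: int = 65536,
) -> PotentialGrid:
    """Evaluate the screened-Coulomb potential of ``structure`` on ``spec``."""
    params = params or ElectrostaticsParams()
    q = structure.charges()
    if np.all(q == 0):
        warnings.warn(
            f"{structure.label}: all charges are zero; potential grid is identically zero",
            stacklevel=2,
        )
    pos = structure.coords()
    pts = spec.points()
    kappa = params.kappa
    pref = params.coulomb_constant / params.epsilon
    floor = params.singularity_floor
    out = np.empty(len(pts), dtype=float)
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - pos[None, :, :], axis=2)
        np.maximum(d, floor, out=d)
        if kappa > 0:
            out[start : start + len(block)] = pref * (q * np.exp(-kappa * d) / d).sum(axis=1)
        else:
            out[start : start + len(block)] = pref * (q / d).sum(axis=1)
    return PotentialGrid(spec=spec, values=out.reshape(spec.shape), label=structure.label)


def multipole_summary(structure: Structure) -> MultipoleSummary:
    """Net charge and dipole about the |q|-weighted (fallback geometric) centroid."""
    q = structure.charges()
    pos = structure.coords()
    net = float(q.sum())
    weights = np.abs(q)
    if weights.sum() > 0:
        center = (weights[:, None] * pos).sum(axis=0) / weights.sum()
    else:
        center = pos.mean(axis=0)
    dipole = (q[:, None] * (pos - center)).sum(axis=0)
    return MultipoleSummary(
        net_charge=net, dipole=tuple(map(float, dipole)), center=tuple(map(float, center))
    )


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Deterministic, roughly uniform point set on a sphere about the origin."""
    i = np.arange(n, dtype=float)
    golden = (1 + np.sqrt(5.0)) / 2
    z = 1 - 2 * (i + 0.5) / n
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(np.clip(1 - z**2, 0.0, 1.0))
    return radius * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _truncated_potential(summary: MultipoleSummary, pts: np.ndarray) -> np.ndarray:
    center = np.asarray(summary.center, dtype=float)
    mu = np.asarray(summary.dipole, dtype=float)
    rel = pts - center
    dist = np.linalg.norm(rel, axis=1)
    return summary.net_charge / dist + (rel @ mu) / dist**3


def prescreen_similarity(
    a: MultipoleSummary,
    b: MultipoleSummary,
    shell_radius: float = 30.0,
    n_points: int = 64,
) -> float:
    """Hodgkin index of the truncated (monopole + dipole) fields.

    Both fields are sampled on one deterministic spherical shell of
    ``shell_radius`` about the shared-frame origin.  Fast, grid-free,
    advisory only.
    """
    if shell_radius <= 0:
        raise ValueError("shell_radius must be > 0")
    if n_points < 12:
        raise ValueError("n_points must be >= 12")
    pts = _fibonacci_sphere(n_points, shell_radius)
    fa = _truncated_potential(a, pts)
    fb = _truncated_potential(b, pts)
    denom = float(fa @ fa + fb @ fb)
    if denom == 0:
        raise DataError("prescreen similarity undefined: both multipole fields are zero")
    return float(np.clip(2.0 * (fa @ fb) / denom, -1.0, 1.0))
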