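"""Molecular skin and cylindrical focus-region masks.

The similarity statistic is never evaluated over the whole lattice: it
is restricted to (i) the molecular *skin* — lattice points strictly
outside the solvent-accessible surface (atom radius + probe radius) but
within a set thickness of it — and (ii) a cylinder over the
peptide-binding cleft that excludes the electrostatically near-identical
framework regions shared by all complexes.  Comparison of a pair uses
the intersection of both skins with the cylinder.

Boundary convention (fixed so that point counts are reproducible):
strictly outside the solvent-accessible surface (``>``), closed at the
outer skin bound and on the cylinder surface (``<=``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, EmptyMaskError
from .electrostatics import GridSpec
from .structure import Structure


@dataclass(frozen=True)
class SkinParams:
    """Probe radius sigma and skin thickness delta, Angstrom."""

    probe_radius: float = 1.0
    thickness: float = 25.0

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.thickness <= 0:
            raise ValueError("skin thickness must be > 0")


@dataclass(frozen=True)
class CylinderRegion:
    """The focus cylinder: center, unit axis, radius, length (Angstrom)."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float = 40.0
    length: float = 33.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("cylinder radius and length must be > 0")
        a = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(a)
        if norm == 0 or not np.all(np.isfinite(a)):
            raise ValueError("cylinder axis must be a non-zero finite vector")
        object.__setattr__(self, "axis", tuple(float(v) for v in a / norm))


@dataclass(frozen=True)
class RegionMask:
    """Boolean mask congruent with one :class:`GridSpec`."""

    spec: GridSpec
    included: np.ndarray

    def __post_init__(self) -> None:
        if self.included.shape != self.spec.shape:
            raise ValueError("mask shape does not match grid spec dims")
        if self.included.dtype != bool:
            object.__setattr__(self, "included", self.included.astype(bool))

    @property
    def count(self) -> int:
        return int(self.included.sum())


def _require_same_spec(*masks: RegionMask) -> GridSpec:
    spec = masks[0].spec
    for m in masks[1:]:
        if m.spec != spec:
            raise DataError("masks with different grid specs cannot be combined")
    return spec


def compute_skin_mask(
    structure: Structure,
    spec: GridSpec,
    params: SkinParams | None = None,
    chunk: int = 65536,
) -> RegionMask:
    """Skin mask: 0 < min_i(|g - r_i| - (R_i + sigma)) <= delta.

    ``R_i`` are the assigned van der Waals radii.  Raises
    :class:`EmptyMaskError` if no lattice point qualifies.
    """
    params = params or SkinParams()
    pos = structure.coords()
    reach = structure.radii() + params.probe_radius
    pts = spec.points()
    signed = np.empty(len(pts), dtype=float)
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - pos[None, :, :], axis=2)
        signed[start : start + len(block)] = (d - reach[None, :]).min(axis=1)
    included = (signed > 0) & (signed <= params.thickness)
    mask = RegionMask(spec=spec, included=included.reshape(spec.shape))
    if mask.count == 0:
        raise EmptyMaskError(f"{structure.label}: empty skin mask")
    return mask


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Fix the sign of an axis vector deterministically (+z, then +y, +x)."""
    for comp in (2, 1, 0):
        if abs(v[comp]) > 1e-12:
            return v if v[comp] > 0 else -v
    return v


def place_cylinder(
    reference: Structure,
    center: tuple[float, float, float] | None = None,
    axis: tuple[float, float, float] | None = None,
    radius: float = 40.0,
    length: float = 33.0,
    peptide_chain: str | None = None,
) -> CylinderRegion:
    """Place the focus cylinder over the cleft of the reference structure.

    Explicit ``center``/``axis`` override auto-placement.  Otherwise the
    center is the centroid of the peptide-chain atoms and the axis is
    the unit normal of the least-squares plane through the peptide
    Calpha atoms — the cleft-top normal, so the cylinder's flat faces
    parallel the cleft plane (which is why the radius may exceed the
    length).
    """
    if center is not None and axis is not None:
        return CylinderRegion(
            center=tuple(map(float, center)), axis=tuple(map(float, axis)),
            radius=radius, length=length,
        )
    chain = reference.peptide_chain(peptide_chain)
    chain_atoms = [a for a in reference.atoms if a.chain_id == chain]
    pos = np.array([[a.x, a.y, a.z] for a in chain_atoms])
    if center is None:
        center = tuple(map(float, pos.mean(axis=0)))
    if axis is None:
        ca = np.array(
            [[a.x, a.y, a.z] for a in chain_atoms if a.atom_name == "CA"]
        )
        if len(ca) < 3:
            raise DataError(
                f"{reference.label}: fewer than 3 peptide Calpha atoms; "
                "supply the cylinder axis explicitly"
            )
        centered = ca - ca.mean(axis=0)
        _, sv, vt = np.linalg.svd(centered, full_matrices=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DataError(
                f"{reference.label}: peptide Calpha atoms are collinear; "
                "supply the cylinder axis explicitly"
            )
        axis = tuple(map(float, _canonical_sign(vt[2])))
    return CylinderRegion(center=center, axis=axis, radius=radius, length=length)


def cylinder_mask(spec: GridSpec, cylinder: CylinderRegion) -> RegionMask:
    """Mask of lattice points inside the cylinder (closed boundaries)."""
    pts = spec.points()
    center = np.asarray(cylinder.center, dtype=float)
    axis = np.asarray(cylinder.axis, dtype=float)
    rel = pts - center
    axial = rel @ axis
    radial_sq = (rel**2).sum(axis=1) - axial**2
    included = (np.abs(axial) <= cylinder.length / 2) & (
        radial_sq <= cylinder.radius**2 + 1e-9
    )
    mask = RegionMask(spec=spec, included=included.reshape(spec.shape))
    if mask.count == 0:
        raise EmptyMaskError("cylinder mask contains no lattice points")
    return mask


def pair_mask(
    skin_a: RegionMask,
    skin_b: RegionMask,
    cylinder: RegionMask,
    labels: tuple[str, str] | None = None,
) -> RegionMask:
    """Comparison mask for one pair: skin_a AND skin_b AND cylinder."""
    spec = _require_same_spec(skin_a, skin_b, cylinder)
    combined = skin_a.included & skin_b.included & cylinder.included
    mask = RegionMask(spec=spec, included=combined)
    if mask.count == 0:
        name = f" for pair {labels[0]!r}/{labels[1]!r}" if labels else ""
        raise EmptyMaskError(f"empty comparison mask{name}")
    return mask
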