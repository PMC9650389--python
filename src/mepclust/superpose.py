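"""Rigid-body superposition of complexes onto a shared reference frame.

All complexes in a run are fitted to one reference structure so that
their potential grids live in a single coordinate frame and congruent
lattice points sample the same spatial region on every complex.  The
transform is the least-squares optimal (Kabsch) rotation + translation
over paired atoms; pairing is by shared ``(chain_id, residue_number,
atom_name)`` keys, Calpha-only by default so that side-chain differences
between peptides do not enter the fit.

The superposition is applied twice in sequence per structure.  For an
exact least-squares optimum the second pass is a fixed point (it moves
coordinates only at floating-point level); both passes' RMSDs are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DataError, DegenerateFitError
from .structure import Structure

#: rank-deficiency threshold (Angstrom) for the collinearity check
_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class FitResult:
    """An optimal rigid transform ``x -> R x + t`` and its residual."""

    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float  # Angstrom, over paired atoms
    n_paired: int


def _atom_key_map(s: Structure, selection: str) -> dict[tuple[str, int, str], int]:
    keys: dict[tuple[str, int, str], int] = {}
    for i, a in enumerate(s.atoms):
        if selection == "ca" and a.atom_name != "CA":
            continue
        keys[(a.chain_id, a.residue_number, a.atom_name)] = i
    return keys


def paired_coords(
    mobile: Structure, reference: Structure, selection: str = "ca"
) -> tuple[np.ndarray, np.ndarray]:
    """Matched coordinate arrays over shared atom keys, in sorted key order."""
    if selection not in ("ca", "all"):
        raise ValueError("selection must be 'ca' or 'all'")
    mk = _atom_key_map(mobile, selection)
    rk = _atom_key_map(reference, selection)
    shared = sorted(set(mk) & set(rk))
    if not shared:
        raise DataError(
            f"no shared atoms between {mobile.label!r} and reference {reference.label!r}"
        )
    mob = mobile.coords()[[mk[k] for k in shared]]
    ref = reference.coords()[[rk[k] for k in shared]]
    return mob, ref


def kabsch_fit(
    mobile: Structure, reference: Structure, selection: str = "ca"
) -> FitResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Raises :class:`DegenerateFitError` for fewer than 3 pairs or a
    collinear pairing (the rotation about the line is unidentifiable).
    """
    mob, ref = paired_coords(mobile, reference, selection)
    n = len(mob)
    if n < 3:
        raise DegenerateFitError(
            f"{mobile.label}: only {n} paired atoms; >=3 non-collinear pairs required"
        )
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] <= _COLLINEAR_TOL * max(1.0, sv[0]):
        raise DegenerateFitError(f"{mobile.label}: paired atoms are collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    rotation = rot.as_matrix()
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return FitResult(rotation=rotation, translation=translation, rmsd=rmsd, n_paired=n)


def apply_fit(structure: Structure, fit: FitResult) -> Structure:
    return structure.transformed(fit.rotation, fit.translation)


def fit_all(
    structures: list[Structure],
    reference: Structure,
    selection: str = "ca",
) -> tuple[list[Structure], pd.DataFrame]:
    """Fit every structure to the reference in two successive passes.

    Returns the fitted structures (input order) and an RMSD table with
    columns ``label, n_paired, rmsd_pass1, rmsd_pass2``.  The reference
    itself is never modified.
    """
    fitted: list[Structure] = []
    rows = []
    for s in structures:
        fit1 = kabsch_fit(s, reference, selection)
        moved = apply_fit(s, fit1)
        fit2 = kabsch_fit(moved, reference, selection)
        moved = apply_fit(moved, fit2)
        rows.append(
            {
                "label": s.label,
                "n_paired": fit1.n_paired,
                "rmsd_pass1": fit1.rmsd,
                "rmsd_pass2": fit2.rmsd,
            }
        )
        fitted.append(moved)
    return fitted, pd.DataFrame(rows)
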