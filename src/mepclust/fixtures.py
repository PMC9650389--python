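"""Synthetic toy pMHC-like complexes with planted electrostatic structure.

Real inputs to the pipeline are modelled peptide-MHC class I complexes.
For testing, this module builds minimal stand-ins that preserve exactly
the features the pipeline relies on:

* a *scaffold* — a neutral slab of pseudo-atoms playing the MHC cleft
  floor, byte-identical across all fixtures so that every similarity
  difference is attributable to the peptide (mirroring the rationale for
  focusing the comparison on the cleft: the identical surroundings
  contribute no discriminating signal);
* a *pseudo-peptide* — nine charged pseudo-residues at 3.8 A Calpha
  spacing along x in the cleft plane (nonamers are the canonical epitope
  length), slightly zig-zagged in y so the least-squares peptide plane
  is well defined for cylinder auto-placement;
* chain labelling (scaffold chain A with 40 residues, peptide chain P
  with 9) chosen so peptide-chain auto-detection works.

Pseudo-residues use registered fixture residue types (``FX*``) in a
:class:`~mepclust.structure.ChargeModel` rather than mimicking real
amino acids, decoupling fixture ground truth from the biological charge
table.  Benchmark sets plant ``n_groups`` mutually orthogonal +/- charge
sign patterns (rows of a Hadamard matrix, scaled by the separation and
zero-padded to 9 positions); within-group members differ only by
Gaussian coordinate jitter of the peptide atoms.  Everything is
deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import hadamard

from .errors import DataError
from .structure import AtomRecord, ChargeModel, Structure

#: peptide Calpha spacing along x, Angstrom
_CA_SPACING = 3.8
#: y zig-zag amplitude keeping the peptide plane non-degenerate
_ZIGZAG = 0.8
#: pseudo-atom van der Waals radius
_PSEUDO_RADIUS = 1.7

SCAFFOLD_RESIDUE = "SCF"
SCAFFOLD_CHAIN = "A"
PEPTIDE_CHAIN = "P"


@dataclass(frozen=True)
class MotifSpec:
    """A nonamer charge pattern: one charge (e) per peptide position."""

    charges: tuple[float, ...]
    jitter: float = 0.0  # Gaussian sigma per coordinate, Angstrom
    group_id: int = 0

    def __post_init__(self) -> None:
        if len(self.charges) != 9:
            raise DataError(f"motif must have 9 positions, got {len(self.charges)}")
        if self.jitter < 0:
            raise DataError("jitter must be >= 0")


def _charge_residue_names(levels: list[float]) -> dict[float, str]:
    """Stable mapping of distinct charge values to fixture residue names."""
    uniq = sorted(set(levels))
    if len(uniq) > 26:
        raise DataError("too many distinct charge levels for fixture residue naming")
    return {q: f"FX{chr(ord('A') + i)}" for i, q in enumerate(uniq)}


def fixture_charge_model(levels: list[float]) -> tuple[ChargeModel, dict[float, str]]:
    """Charge model with scaffold + per-level pseudo-residue entries."""
    model = ChargeModel(zwitterionic_termini=False)
    model.register(SCAFFOLD_RESIDUE, "CA", 0.0, _PSEUDO_RADIUS)
    names = _charge_residue_names(levels)
    for q, res in names.items():
        model.register(res, "CA", q, _PSEUDO_RADIUS)
    return model, names


def _scaffold_atoms() -> list[AtomRecord]:
    """The shared neutral slab: 10 x 4 pseudo-atoms at z = -4."""
    atoms = []
    serial = 1
    resnum = 1
    xs = (np.arange(10) - 4.5) * 3.5
    ys = (np.arange(4) - 1.5) * 3.5
    for y in ys:
        for x in xs:
            atoms.append(
                AtomRecord(
                    "ATOM", serial, "CA", SCAFFOLD_RESIDUE, SCAFFOLD_CHAIN, resnum,
                    float(x), float(y), -4.0,
                    charge=0.0, radius=_PSEUDO_RADIUS,
                )
            )
            serial += 1
            resnum += 1
    return atoms


def generate_toy_complex(
    motif: MotifSpec,
    seed: int,
    label: str = "toy",
    charge_names: dict[float, str] | None = None,
) -> tuple[Structure, ChargeModel]:
    """One toy complex: neutral scaffold + charged pseudo-peptide.

    Deterministic given (motif, seed); jitter is the only stochastic
    element and perturbs peptide atom coordinates only.  The returned
    structure already carries the charges/radii the accompanying charge
    model would assign, so both the direct path and the
    write-PDB-then-assign pipeline path agree.
    """
    if charge_names is None:
        model, charge_names = fixture_charge_model(list(motif.charges))
    else:
        missing = set(motif.charges) - set(charge_names)
        if missing:
            raise DataError(f"charge_names missing levels: {sorted(missing)}")
        charge_names = dict(charge_names)
        model = ChargeModel(zwitterionic_termini=False)
        model.register(SCAFFOLD_RESIDUE, "CA", 0.0, _PSEUDO_RADIUS)
        for q, res in charge_names.items():
            model.register(res, "CA", q, _PSEUDO_RADIUS)
    atoms = _scaffold_atoms()
    serial = len(atoms) + 1
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    offsets = rng.normal(0.0, motif.jitter, size=(9, 3)) if motif.jitter > 0 else np.zeros((9, 3))
    for k, q in enumerate(motif.charges):
        x = (k - 4) * _CA_SPACING + offsets[k, 0]
        y = _ZIGZAG * (-1) ** k + offsets[k, 1]
        z = 0.0 + offsets[k, 2]
        atoms.append(
            AtomRecord(
                "ATOM", serial, "CA", charge_names[q], PEPTIDE_CHAIN, k + 1,
                float(x), float(y), float(z),
                charge=float(q), radius=_PSEUDO_RADIUS,
            )
        )
        serial += 1
    return Structure(label, atoms), model


def builtin_reference() -> Structure:
    """The canonical reference frame: a zero-charge toy complex.

    Cleft plane = xy-plane, peptide axis = x-axis, cleft centroid near
    the origin; generated deterministically so all runs share one frame.
    """
    ref, _ = generate_toy_complex(
        MotifSpec(charges=(0.0,) * 9, jitter=0.0), seed=0, label="reference"
    )
    return ref


def group_motifs(n_groups: int, separation: float) -> list[tuple[float, ...]]:
    """Mutually orthogonal sign patterns scaled by ``separation``.

    Rows 1..n of an 8x8 Hadamard matrix (row 0, all ones, is skipped so
    every motif is net-neutral), zero-padded to 9 positions.
    """
    if n_groups > 7:
        raise DataError("at most 7 mutually orthogonal net-neutral motifs are available")
    if separation <= 0:
        raise DataError("motif separation must be > 0")
    had = hadamard(8)
    return [
        tuple(float(separation * v) for v in had[g + 1]) + (0.0,)
        for g in range(n_groups)
    ]


def generate_benchmark_set(
    out_dir: str | Path,
    n_groups: int = 3,
    per_group: int = 3,
    motif_separation: float = 1.0,
    jitter: float = 0.2,
    seed: int = 0,
) -> tuple[list[Path], dict[str, int], ChargeModel]:
    """A benchmark of planted groups, written as PDB files + truth labels.

    Writes one PDB per complex, ``truth.tsv`` (label, group) and
    ``charges.tsv`` (the fixture charge table) into ``out_dir``.
    Returns the file paths (generation order), the truth mapping and the
    charge model.  Byte-identical when regenerated with the same
    parameters.
    """
    if n_groups < 2 or per_group < 2:
        raise DataError("need n_groups >= 2 and per_group >= 2")
    if n_groups * per_group < 3:
        raise DataError("benchmark must contain at least 3 complexes")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    motifs = group_motifs(n_groups, motif_separation)
    levels = sorted({q for m in motifs for q in m})
    model, names = fixture_charge_model(levels)

    paths: list[Path] = []
    truth: dict[str, int] = {}
    for g, motif_charges in enumerate(motifs):
        for m in range(per_group):
            label = f"g{g + 1}m{m + 1}"
            member_seed = int(
                np.random.SeedSequence((seed, g, m)).generate_state(1)[0] % (2**31)
            )
            motif = MotifSpec(charges=motif_charges, jitter=jitter, group_id=g)
            structure, _ = generate_toy_complex(
                motif, member_seed, label=label, charge_names=names
            )
            path = out / f"{label}.pdb"
            structure.write_pdb(path)
            paths.append(path)
            truth[label] = g

    with open(out / "truth.tsv", "w") as fh:
        fh.write("label\tgroup\n")
        for label, g in truth.items():
            fh.write(f"{label}\t{g}\n")
    with open(out / "charges.tsv", "w") as fh:
        fh.write("# fixture charge table: residue_name, atom_name, charge, radius\n")
        fh.write(f"{SCAFFOLD_RESIDUE}\tCA\t0.0\t{_PSEUDO_RADIUS}\n")
        for q, res in sorted(names.items(), key=lambda kv: kv[1]):
            fh.write(f"{res}\tCA\t{q}\t{_PSEUDO_RADIUS}\n")
    return paths, truth, model
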