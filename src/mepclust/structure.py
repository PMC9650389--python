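"""PDB structure reading, sanitising, writing, and charge/radius assignment.

Two coordinate dialects are accepted:

* fixed-column PDB v3.3 (``ATOM``/``HETATM`` records, coordinates in
  columns 31-54), and
* a stripped whitespace-delimited dialect in which every line carries
  exactly nine fields: record type, serial, atom name, residue name,
  chain id, residue number, x, y, z.

The second dialect is what :func:`preprocess_pdb` emits: modelling
pipelines often attach occupancy/B-factor/charge columns that downstream
grid tools choke on, so sanitising keeps only the nine fields that carry
structural information.  The writer always emits fixed-column PDB.

Partial charges and van der Waals radii are not part of either dialect;
they are assigned afterwards from a :class:`ChargeModel` — by default a
formal-charge table (carboxylates -1, LYS/ARG +1, HIS neutral,
zwitterionic termini) with a per-element radius table.  This is
deliberately coarse: the downstream similarity statistic is evaluated on
a solvent shell well away from the surface, where the field is dominated
by the placement of net charges rather than by sub-elementary partial
charge detail.  A custom table can be merged in for finer models.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError, ParseError

_COORD_RECORDS = ("ATOM", "HETATM")

#: default van der Waals radii by element, Angstrom
DEFAULT_ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}


@dataclass
class AtomRecord:
    """One coordinate record with assigned charge and radius."""

    record_type: str
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    x: float
    y: float
    z: float
    charge: float = 0.0  # elementary charges
    radius: float = 0.0  # Angstrom

    def __post_init__(self) -> None:
        if self.record_type not in _COORD_RECORDS:
            raise ValueError(f"record_type must be ATOM or HETATM, got {self.record_type!r}")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates on atom serial {self.serial}")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")

    @property
    def element(self) -> str:
        """Element symbol inferred from the atom name (first letter)."""
        for ch in self.atom_name:
            if ch.isalpha():
                return ch.upper()
        return ""


@dataclass
class Structure:
    """An ordered collection of atom records under a unique label."""

    label: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise DataError(f"structure {self.label!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def total_charge(self) -> float:
        return float(self.charges().sum())

    def chain_residues(self, chain_id: str) -> list[int]:
        """Residue numbers of a chain, in order of first appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.residue_number, None)
        return list(seen)

    def peptide_chain(self, override: str | None = None) -> str:
        """Identify the peptide chain: shortest chain of 8-11 residues.

        Nonameric epitopes dominate the intended input class; the 8-11
        window tolerates octamers through undecamers.  ``override`` wins.
        """
        if override is not None:
            if override not in self.chains:
                raise DataError(f"{self.label}: no chain {override!r}")
            return override
        candidates = [
            (len(self.chain_residues(c)), c)
            for c in self.chains
            if 8 <= len(self.chain_residues(c)) <= 11
        ]
        if not candidates:
            raise DataError(
                f"{self.label}: no chain with 8-11 residues; "
                "set the peptide chain or the cylinder placement explicitly"
            )
        return min(candidates)[1]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with coordinates mapped to ``R x + t``."""
        xyz = self.coords() @ np.asarray(rotation, dtype=float).T + np.asarray(
            translation, dtype=float
        )
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return Structure(self.label, atoms)

    def to_pdb(self) -> str:
        """Render as fixed-column PDB v3.3 coordinate section."""
        lines = []
        for a in self.atoms:
            name = a.atom_name
            # PDB convention: names of <4 chars start in column 14
            name_field = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"{a.record_type:<6s}{a.serial:>5d} {name_field:<4s} "
                f"{a.residue_name:<3s} {a.chain_id:1s}{a.residue_number:>4d}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"

    def write_pdb(self, path: str | Path) -> None:
        Path(path).write_text(self.to_pdb())


def _parse_fixed_column(line: str) -> AtomRecord | None:
    """Try to parse a fixed-column v3.3 coordinate record; None if not one."""
    if len(line) < 54:
        return None
    try:
        record = line[:6].strip()
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        return None
    if not atom_name or not residue_name:
        return None
    return AtomRecord(record, serial, atom_name, residue_name, chain_id, residue_number, x, y, z)


def _parse_nine_field(line: str) -> AtomRecord | None:
    parts = line.split()
    if len(parts) != 9:
        return None
    try:
        return AtomRecord(
            parts[0],
            int(parts[1]),
            parts[2],
            parts[3],
            parts[4],
            int(parts[5]),
            float(parts[6]),
            float(parts[7]),
            float(parts[8]),
        )
    except ValueError:
        return None


def _altloc_kept(line: str) -> bool:
    """Keep altloc ' ' or 'A' on fixed-column records; drop B, C, ..."""
    if len(line) > 16 and line[16] not in (" ", "A"):
        return False
    return True


def parse_structure(source: str | Path, label: str | None = None) -> Structure:
    """Parse a PDB-like file or text block into a :class:`Structure`.

    ``source`` may be a path or raw text.  Non-coordinate records
    (REMARK, SEQRES, TER, ANISOU, ...) are ignored; alternate locations
    other than ' '/'A' are dropped; hydrogens present in the input are
    kept as ordinary atoms but never added.
    """
    path: Path | None = None
    if isinstance(source, Path):
        path = source
    elif isinstance(source, str) and "\n" not in source and Path(source).exists():
        path = Path(source)
    text = path.read_text() if path is not None else str(source)
    if label is None:
        label = path.stem if path is not None else "structure"

    atoms: list[AtomRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        head = stripped.split(None, 1)[0]
        if head not in _COORD_RECORDS:
            continue
        rec = None
        if line[:6].strip() in _COORD_RECORDS:
            rec = _parse_fixed_column(line)
            if rec is not None and not _altloc_kept(line):
                continue
        if rec is None:
            rec = _parse_nine_field(stripped)
        if rec is None:
            raise ParseError(f"{label}: unparseable coordinate record at line {lineno}")
        atoms.append(rec)
    if not atoms:
        raise ParseError(f"{label}: no coordinate records found")
    return Structure(label, atoms)


def preprocess_pdb(text: str) -> str:
    """Sanitise a PDB text block to the nine-field dialect.

    Every surviving line is a coordinate record with exactly nine
    whitespace-separated fields (record type, serial, atom name, residue
    name, chain id, residue number, x, y, z); all other record types are
    dropped.  Idempotent, order-preserving, coordinates kept to 3
    decimals.
    """
    out: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        head = stripped.split(None, 1)[0]
        if head not in _COORD_RECORDS:
            continue
        rec = None
        if line[:6].strip() in _COORD_RECORDS:
            rec = _parse_fixed_column(line)
            if rec is not None and not _altloc_kept(line):
                continue
        if rec is None:
            rec = _parse_nine_field(stripped)
        if rec is None:
            raise ParseError(f"unparseable coordinate record at line {lineno}")
        out.append(
            f"{rec.record_type} {rec.serial} {rec.atom_name} {rec.residue_name} "
            f"{rec.chain_id} {rec.residue_number} "
            f"{rec.x:.3f} {rec.y:.3f} {rec.z:.3f}"
        )
    if not out:
        raise ParseError("no coordinate records survive preprocessing")
    return "\n".join(out) + "\n"


def preprocess_structure_file(in_path: str | Path, out_path: str | Path) -> Path:
    """File-level wrapper of :func:`preprocess_pdb`."""
    out = Path(out_path)
    out.write_text(preprocess_pdb(Path(in_path).read_text()))
    return out


class ChargeModel:
    """Lookup table assigning per-atom partial charge and radius.

    Charges are keyed by ``(residue_name, atom_name)``; radii fall back
    to a per-element table.  ``policy`` controls unknown atoms: ``zero``
    assigns charge 0 (radius from the element table), ``error`` raises,
    listing the offenders.
    """

    def __init__(
        self,
        charges: dict[tuple[str, str], float] | None = None,
        radii: dict[tuple[str, str], float] | None = None,
        element_radii: dict[str, float] | None = None,
        policy: str = "zero",
        zwitterionic_termini: bool = True,
        default_radius: float = 1.7,
    ) -> None:
        if policy not in ("zero", "error"):
            raise ValueError("policy must be 'zero' or 'error'")
        self.charges = dict(charges or {})
        self.radii = dict(radii or {})
        self.element_radii = dict(element_radii or DEFAULT_ELEMENT_RADII)
        self.policy = policy
        self.zwitterionic_termini = zwitterionic_termini
        self.default_radius = default_radius

    def register(
        self, residue_name: str, atom_name: str, charge: float, radius: float | None = None
    ) -> None:
        """Add (or override) one table entry, e.g. for synthetic residues."""
        self.charges[(residue_name, atom_name)] = float(charge)
        if radius is not None:
            self.radii[(residue_name, atom_name)] = float(radius)

    def merge_tsv(self, path: str | Path) -> None:
        """Merge entries from a TSV of residue_name, atom_name, charge, radius."""
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise DataError(f"charge table {path}: bad row at line {lineno}")
            radius = float(parts[3]) if len(parts) == 4 and parts[3] else None
            self.register(parts[0], parts[1], float(parts[2]), radius)

    @classmethod
    def default(cls) -> "ChargeModel":
        """The shipped formal-charge model."""
        model = cls()
        table = importlib.resources.files("mepclust.data").joinpath("charges.tsv")
        for line in table.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            radius = float(parts[3]) if len(parts) > 3 and parts[3] else None
            model.register(parts[0], parts[1], float(parts[2]), radius)
        return model

    def _radius_for(self, atom: AtomRecord) -> float | None:
        key = (atom.residue_name, atom.atom_name)
        if key in self.radii:
            return self.radii[key]
        return self.element_radii.get(atom.element, self.default_radius)

    def assign(self, structure: Structure) -> Structure:
        """Return a copy of ``structure`` with charges and radii populated."""
        unknown: list[tuple[str, str]] = []
        atoms: list[AtomRecord] = []
        for a in structure.atoms:
            key = (a.residue_name, a.atom_name)
            if key in self.charges:
                q = self.charges[key]
            else:
                q = 0.0
                if self.policy == "error" and a.record_type == "ATOM":
                    unknown.append(key)
            atoms.append(replace(a, charge=q, radius=self._radius_for(a)))
        if unknown:
            offenders = ", ".join(f"{r}/{n}" for r, n in sorted(set(unknown))[:10])
            raise DataError(
                f"{structure.label}: unknown (residue, atom) pairs under policy=error: {offenders}"
            )
        out = Structure(structure.label, atoms)
        if self.zwitterionic_termini:
            self._apply_termini(out)
        return out

    def _apply_termini(self, s: Structure) -> None:
        # +1 on the backbone N of the first residue, -1 on OXT (or O) of
        # the last; applied only to chains that look like polypeptides.
        for chain in s.chains:
            residues = s.chain_residues(chain)
            if not residues:
                continue
            first, last = residues[0], residues[-1]
            chain_atoms = [a for a in s.atoms if a.chain_id == chain and a.record_type == "ATOM"]
            n_atom = next(
                (a for a in chain_atoms if a.residue_number == first and a.atom_name == "N"), None
            )
            last_atoms = {a.atom_name: a for a in chain_atoms if a.residue_number == last}
            c_atom = last_atoms.get("OXT") or last_atoms.get("O")
            if n_atom is None or c_atom is None:
                continue  # not a polypeptide chain (e.g. pseudo-atom scaffold)
            n_atom.charge += 1.0
            c_atom.charge -= 1.0


def assign_charges_radii(structure: Structure, model: ChargeModel | None = None) -> Structure:
    """Assign charges and radii; convenience wrapper over :meth:`ChargeModel.assign`."""
    return (model or ChargeModel.default()).assign(structure)
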