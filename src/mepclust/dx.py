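"""OpenDX scalar-field export for potential grids and region masks.

The OpenDX "regular positions, regular connections" format is the de
facto interchange format for volumetric electrostatics data; grids and
0/1 masks written here load directly into PyMOL, VMD or Chimera for
visual checks of the skin and focus-region geometry.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .electrostatics import PotentialGrid
from .regions import RegionMask


def _write_dx(path: Path, origin, spacing: float, dims, values: np.ndarray, comment: str) -> None:
    nx, ny, nz = dims
    flat = values.reshape(-1)  # C order: x fastest-varying last, per DX convention
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {origin[0]:.6g} {origin[1]:.6g} {origin[2]:.6g}\n")
        fh.write(f"delta {spacing:.6g} 0 0\n")
        fh.write(f"delta 0 {spacing:.6g} 0\n")
        fh.write(f"delta 0 0 {spacing:.6g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} data follows\n"
        )
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def write_grid_dx(grid: PotentialGrid, path: str | Path) -> Path:
    """Write a potential grid (kcal/mol/e) as an OpenDX scalar field."""
    path = Path(path)
    _write_dx(
        path, grid.spec.origin, grid.spec.spacing, grid.spec.dims, grid.values,
        f"electrostatic potential, {grid.label}",
    )
    return path


def write_mask_dx(mask: RegionMask, path: str | Path, name: str = "mask") -> Path:
    """Write a region mask as a 0/1 OpenDX scalar field."""
    path = Path(path)
    _write_dx(
        path, mask.spec.origin, mask.spec.spacing, mask.spec.dims,
        mask.included.astype(float), name,
    )
    return path
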