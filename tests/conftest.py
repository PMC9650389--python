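"""Shared fixtures: toy structures and one session-scoped benchmark run."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from mepclust import (
    AtomRecord,
    Structure,
    generate_benchmark_set,
    run_pipeline,
    validate_config,
)

#: study conditions of the synthetic recovery benchmark
BENCHMARK = dict(
    n_groups=3,
    per_group=3,
    motif_separation=1.0,
    jitter=0.2,
    nboot=1000,
    seed=1,
    grid_spacing=2.0,
    cylinder_radius=12.0,
    cylinder_length=14.0,
)


def structure_from_coords(
    coords, label="toy", chain="A", atom_name="CA", residue_name="GLY", charges=None
) -> Structure:
    """Build a minimal structure with one atom per residue."""
    coords = np.asarray(coords, dtype=float)
    charges = np.zeros(len(coords)) if charges is None else np.asarray(charges, float)
    atoms = [
        AtomRecord(
            "ATOM", i + 1, atom_name, residue_name, chain, i + 1,
            float(p[0]), float(p[1]), float(p[2]),
            charge=float(q), radius=1.7,
        )
        for i, (p, q) in enumerate(zip(coords, charges))
    ]
    return Structure(label, atoms)


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory):
    """Generate the planted-group benchmark and run the pipeline twice.

    Two runs with the same seed support the determinism checks; the
    reduced cylinder and 2 A grid keep runtime modest while retaining
    the planted signal.
    """
    base = tmp_path_factory.mktemp("benchmark")
    paths, truth, _ = generate_benchmark_set(
        base / "in",
        n_groups=BENCHMARK["n_groups"],
        per_group=BENCHMARK["per_group"],
        motif_separation=BENCHMARK["motif_separation"],
        jitter=BENCHMARK["jitter"],
        seed=BENCHMARK["seed"],
    )

    def config_for(out_dir):
        return validate_config(
            dict(
                inputs=[str(p) for p in paths],
                out_dir=str(out_dir),
                charge_table=str(base / "in" / "charges.tsv"),
                cylinder_radius=BENCHMARK["cylinder_radius"],
                cylinder_length=BENCHMARK["cylinder_length"],
                grid_spacing=BENCHMARK["grid_spacing"],
                nboot=BENCHMARK["nboot"],
                seed=BENCHMARK["seed"],
            )
        )

    report1 = run_pipeline(config_for(base / "out1"))
    report2 = run_pipeline(config_for(base / "out2"))
    return SimpleNamespace(
        truth=truth,
        paths=paths,
        report=report1,
        report2=report2,
        out1=base / "out1",
        out2=base / "out2",
        base=base,
    )
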