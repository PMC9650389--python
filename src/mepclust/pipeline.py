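"""End-to-end orchestration: PDB files in, clustered similarity out.

Stage order: preprocess -> parse -> assign charges -> fit (twice) ->
grid spec -> potentials -> skins + cylinder -> SI matrix -> clustering +
multiscale bootstrap -> AU -> significance flagging -> outputs.

Outputs written to the run directory: ``si_matrix.tsv``,
``dist_matrix.tsv``, ``points_used.tsv``, ``fit_rmsd.tsv``,
``tree.nwk``, ``nodes.tsv``, ``report.json``, ``run.log``.  The report
embeds the fully resolved configuration and seed, so a run can be
reproduced exactly from its report alone.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import DEFAULT_SCALES, ClusterTree, au_from_bp, multiscale_bootstrap
from .electrostatics import (
    ElectrostaticsParams,
    build_grid_spec,
    compute_potential_grid,
    multipole_summary,
    prescreen_similarity,
)
from .errors import ConfigError, DataError, MepclustError
from .fixtures import builtin_reference
from .regions import SkinParams, compute_skin_mask, cylinder_mask, place_cylinder
from .similarity import SimilarityMatrix, similarity_matrix
from .structure import ChargeModel, Structure, parse_structure, preprocess_pdb
from .superpose import fit_all

logger = logging.getLogger("mepclust")


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration with the shipped defaults."""

    inputs: tuple[str, ...] = ()
    out_dir: str = "out"
    reference: str = "builtin"  # or a PDB path
    peptide_chain: str | None = None
    pairing: str = "ca"  # "ca" | "all"
    probe_radius: float = 1.0  # Angstrom
    skin_thickness: float = 25.0  # Angstrom
    cylinder: str = "auto"  # "auto" | "explicit"
    cylinder_center: tuple[float, float, float] | None = None
    cylinder_axis: tuple[float, float, float] | None = None
    cylinder_radius: float = 40.0  # Angstrom
    cylinder_length: float = 33.0  # Angstrom
    grid_spacing: float = 1.0  # Angstrom
    grid_padding: float = 5.0  # Angstrom
    epsilon: float = 78.4
    ionic_strength: float = 0.05  # mol/L
    temperature: float = 298.15  # K
    cluster_input: str = "si"  # "si" | "d"
    scales: tuple[float, ...] = DEFAULT_SCALES
    nboot: int = 1000
    seed: int = 0
    au_threshold: float = 0.95
    charge_table: str | None = None
    charge_policy: str = "zero"
    zwitterionic_termini: bool = True

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["inputs"] = list(self.inputs)
        out["scales"] = list(self.scales)
        return out


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(raw: dict) -> RunConfig:
    """Resolve a raw key-value config: fill defaults, check ranges.

    Unknown keys raise with a closest-match suggestion; contradictory
    settings (explicit cylinder coordinates under auto placement, or
    vice versa) are rejected.
    """
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        hints = []
        for key in sorted(unknown):
            close = difflib.get_close_matches(key, _KNOWN_KEYS, n=1, cutoff=0.5)
            hints.append(f"{key!r}" + (f" (did you mean {close[0]!r}?)" if close else ""))
        raise ConfigError("unknown config keys: " + ", ".join(hints))
    cfg = RunConfig(**{k: v for k, v in raw.items()})
    cfg.inputs = tuple(str(p) for p in cfg.inputs)
    if cfg.scales is not None:
        cfg.scales = tuple(float(s) for s in cfg.scales)
    if cfg.cylinder_center is not None:
        cfg.cylinder_center = tuple(float(v) for v in cfg.cylinder_center)
    if cfg.cylinder_axis is not None:
        cfg.cylinder_axis = tuple(float(v) for v in cfg.cylinder_axis)

    if cfg.pairing not in ("ca", "all"):
        raise ConfigError("pairing must be 'ca' or 'all'")
    if cfg.cluster_input not in ("si", "d"):
        raise ConfigError("cluster_input must be 'si' or 'd'")
    if cfg.cylinder not in ("auto", "explicit"):
        raise ConfigError("cylinder must be 'auto' or 'explicit'")
    if cfg.charge_policy not in ("zero", "error"):
        raise ConfigError("charge_policy must be 'zero' or 'error'")
    explicit_given = cfg.cylinder_center is not None or cfg.cylinder_axis is not None
    if cfg.cylinder == "auto" and explicit_given:
        raise ConfigError(
            "contradictory cylinder settings: explicit center/axis given under cylinder='auto'"
        )
    if cfg.cylinder == "explicit" and (
        cfg.cylinder_center is None or cfg.cylinder_axis is None
    ):
        raise ConfigError("cylinder='explicit' requires both cylinder_center and cylinder_axis")
    for name in (
        "probe_radius", "skin_thickness", "cylinder_radius", "cylinder_length",
        "grid_spacing", "epsilon", "temperature",
    ):
        if getattr(cfg, name) <= 0 and name != "probe_radius":
            raise ConfigError(f"{name} must be > 0")
    if cfg.probe_radius < 0:
        raise ConfigError("probe_radius must be >= 0")
    if cfg.grid_padding < 0:
        raise ConfigError("grid_padding must be >= 0")
    if cfg.ionic_strength < 0:
        raise ConfigError("ionic_strength must be >= 0")
    if not 0 < cfg.au_threshold < 1:
        raise ConfigError("au_threshold must be in (0, 1)")
    if cfg.nboot < 1:
        raise ConfigError("nboot must be >= 1")
    if any(s <= 0 for s in cfg.scales):
        raise ConfigError("all scales must be > 0")
    return cfg


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict
    version: str
    labels: list[str]
    fit_rmsd: list[dict]
    cylinder: dict
    grid: dict
    flagged_clusters: list[list[str]]
    partition: dict[str, int]
    nodes: list[dict]
    prescreen: list[list[float]] | None = None
    similarity: SimilarityMatrix | None = None
    tree: ClusterTree | None = None

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config": self.config,
            "labels": self.labels,
            "fit_rmsd": self.fit_rmsd,
            "cylinder": self.cylinder,
            "grid": self.grid,
            "flagged_clusters": self.flagged_clusters,
            "partition": self.partition,
            "nodes": self.nodes,
            "prescreen_si": self.prescreen,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _stage(name: str, label: str, start: float) -> None:
    logger.info("%-12s %-16s %.1f ms", name, label, 1000 * (time.perf_counter() - start))


def _load_charge_model(config: RunConfig) -> ChargeModel:
    model = ChargeModel.default()
    model.policy = config.charge_policy
    model.zwitterionic_termini = config.zwitterionic_termini
    if config.charge_table:
        model.merge_tsv(config.charge_table)
    return model


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow and write all outputs to ``out_dir``."""
    if len(config.inputs) < 3:
        raise DataError(
            f"a minimum of three input structures is required, got {len(config.inputs)}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    except MepclustError:
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> RunReport:
    model = _load_charge_model(config)

    structures: list[Structure] = []
    for path in config.inputs:
        label = Path(path).stem
        t0 = time.perf_counter()
        try:
            sanitized = preprocess_pdb(Path(path).read_text())
        except MepclustError as exc:
            raise DataError(f"stage preprocess, structure {label!r}: {exc}") from exc
        _stage("preprocess", label, t0)
        t0 = time.perf_counter()
        try:
            parsed = parse_structure(sanitized, label=label)
        except MepclustError as exc:
            raise DataError(f"stage parse, structure {label!r}: {exc}") from exc
        _stage("parse", label, t0)
        t0 = time.perf_counter()
        try:
            structures.append(model.assign(parsed))
        except MepclustError as exc:
            raise DataError(f"stage charges, structure {label!r}: {exc}") from exc
        _stage("charges", label, t0)
    labels = [s.label for s in structures]
    if len(set(labels)) != len(labels):
        raise DataError(f"duplicate structure labels: {sorted(labels)}")

    if config.reference == "builtin":
        reference = builtin_reference()
    else:
        reference = model.assign(parse_structure(Path(config.reference)))

    t0 = time.perf_counter()
    try:
        fitted, rmsd_table = fit_all(structures, reference, selection=config.pairing)
    except MepclustError as exc:
        raise DataError(f"stage fit: {exc}") from exc
    _stage("fit", "(all)", t0)
    rmsd_table.to_csv(out / "fit_rmsd.tsv", sep="\t", index=False, float_format="%.12g")

    t0 = time.perf_counter()
    cylinder = place_cylinder(
        reference,
        center=config.cylinder_center,
        axis=config.cylinder_axis,
        radius=config.cylinder_radius,
        length=config.cylinder_length,
        peptide_chain=config.peptide_chain,
    )
    spec = build_grid_spec(cylinder, spacing=config.grid_spacing, padding=config.grid_padding)
    cyl_mask = cylinder_mask(spec, cylinder)
    _stage("cylinder", "(reference)", t0)

    eparams = ElectrostaticsParams(
        epsilon=config.epsilon,
        ionic_strength=config.ionic_strength,
        temperature=config.temperature,
    )
    sparams = SkinParams(probe_radius=config.probe_radius, thickness=config.skin_thickness)
    grids = []
    skins = []
    for s in fitted:
        t0 = time.perf_counter()
        try:
            grids.append(compute_potential_grid(s, spec, eparams))
        except MepclustError as exc:
            raise DataError(f"stage potential, structure {s.label!r}: {exc}") from exc
        _stage("potential", s.label, t0)
        t0 = time.perf_counter()
        try:
            skins.append(compute_skin_mask(s, spec, sparams))
        except MepclustError as exc:
            raise DataError(f"stage skin, structure {s.label!r}: {exc}") from exc
        _stage("skin", s.label, t0)

    t0 = time.perf_counter()
    sim = similarity_matrix(grids, skins, cyl_mask)
    _stage("similarity", "(all pairs)", t0)
    sim.write_tsv(out / "si_matrix.tsv", out / "dist_matrix.tsv", out / "points_used.tsv")

    # analytic monopole-dipole prescreen; advisory only
    prescreen: list[list[float]] | None
    try:
        summaries = [multipole_summary(s) for s in fitted]
        n = len(summaries)
        pre = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                pre[i, j] = pre[j, i] = prescreen_similarity(summaries[i], summaries[j])
        prescreen = [[round(float(v), 6) for v in row] for row in pre]
    except MepclustError:
        prescreen = None

    t0 = time.perf_counter()
    data = sim.si_frame() if config.cluster_input == "si" else sim.d_frame()
    table, tree = multiscale_bootstrap(
        data, scales=config.scales, nboot=config.nboot, seed=config.seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # missing-AU warnings are recorded as NaN
        tree.au, tree.bp = au_from_bp(table)
    _stage("cluster", "(bootstrap)", t0)

    flagged = [sorted(s) for s in tree.significant_nodes(config.au_threshold)]
    partition = tree.flagged_partition(config.au_threshold)

    nodes = tree.nodes_frame()
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False, float_format="%.12g")
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")

    report = RunReport(
        config=config.to_dict(),
        version=__version__,
        labels=labels,
        fit_rmsd=rmsd_table.to_dict(orient="records"),
        cylinder={
            "center": list(cylinder.center),
            "axis": list(cylinder.axis),
            "radius": cylinder.radius,
            "length": cylinder.length,
        },
        grid={
            "origin": list(spec.origin),
            "spacing": spec.spacing,
            "dims": list(spec.dims),
            "n_points": spec.n_points,
        },
        flagged_clusters=flagged,
        partition=partition,
        nodes=nodes.to_dict(orient="records"),
        prescreen=prescreen,
        similarity=sim,
        tree=tree,
    )
    (out / "report.json").write_text(report.to_json() + "\n")
    logger.info("run complete: %d complexes, %d flagged clusters", len(labels), len(flagged))
    return report
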