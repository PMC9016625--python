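"""File formats: MRC volumes, JSON annotations, YAML run configuration.

Volumes are stored as CCP4/MRC mode-2 (float32) maps with the voxel size in
the header; missing-wedge metadata travels in a ``<stem>.wedge.json``
sidecar.  Scene annotations are split into two JSON documents so that
measurement code cannot silently read ground truth: a *centerlines* file
(labels and points only — the measurement input) and a *truth* file (the
full generative record).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import gemmi
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .core import Centerline, MissingWedge, ValidationError, Volume3D
from .synth import (
    DefectSpec,
    EndSpec,
    MissingWedge as _MW,  # noqa: F401  (re-exported for config use)
    ParticleSpec,
    ScenePlan,
    SceneTruth,
    make_bundle,
    make_filament,
    make_mt,
)

__all__ = [
    "read_volume",
    "write_volume",
    "write_annotations",
    "read_centerlines",
    "read_truth",
    "RunConfig",
    "plan_from_config",
    "config_hash",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# MRC volumes
# ---------------------------------------------------------------------------

def write_volume(v: Volume3D, path: str | Path) -> None:
    """Write a volume as a CCP4/MRC mode-2 map (voxel size in the header)."""
    path = Path(path)
    m = gemmi.Ccp4Map()
    # gemmi grids are indexed (x, y, z); our data is (z, y, x)
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(v.data.T.astype(np.float32)))
    nz, ny, nx = v.data.shape
    a = 10.0 * v.voxel_size  # Angstrom
    m.grid.unit_cell = gemmi.UnitCell(nx * a, ny * a, nz * a, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))
    if v.wedge is not None:
        sidecar = path.with_suffix(path.suffix + ".wedge.json")
        sidecar.write_text(json.dumps(asdict(v.wedge), indent=1))


def read_volume(path: str | Path) -> Volume3D:
    """Read an MRC volume; wedge metadata from a sidecar JSON if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as e:
        raise ValidationError(f"malformed MRC file {path}: {e}") from e
    grid = m.grid
    vox = np.array([grid.unit_cell.a / grid.nu,
                    grid.unit_cell.b / grid.nv,
                    grid.unit_cell.c / grid.nw]) / 10.0  # nm
    if np.ptp(vox) > 1e-4 * vox.mean():
        raise ValidationError(f"anisotropic voxels unsupported: {vox} nm")
    data = np.ascontiguousarray(np.asarray(grid.array).T)  # -> (z, y, x)
    wedge = None
    sidecar = path.with_suffix(path.suffix + ".wedge.json")
    if sidecar.exists():
        wedge = MissingWedge(**json.loads(sidecar.read_text()))
    return Volume3D(data, voxel_size=float(vox.mean()), wedge=wedge)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def write_annotations(truth: SceneTruth, centerlines_path: str | Path,
                      truth_path: str | Path) -> None:
    """Write the centerline document and the full ground-truth document."""
    lines = []
    for group, key in ((truth.filaments, "filament"), (truth.mts, "mt")):
        for rec in group:
            lines.append({"label": rec["label"], "kind": key,
                          "points": rec["centerline"]})
    labels = [l["label"] for l in lines]
    if len(set(labels)) != len(labels):
        raise ValidationError("centerline labels must be unique")
    doc = {"schema_version": SCHEMA_VERSION, "generator": f"gcmorph {__version__}",
           "seed": truth.seed, "voxel_size": truth.voxel_size, "centerlines": lines}
    Path(centerlines_path).write_text(json.dumps(doc, indent=1))
    full = {"schema_version": SCHEMA_VERSION, "generator": f"gcmorph {__version__}",
            "seed": truth.seed, "voxel_size": truth.voxel_size,
            "filaments": truth.filaments, "crosslinks": truth.crosslinks,
            "branches": truth.branches, "mts": truth.mts}
    Path(truth_path).write_text(json.dumps(full, indent=1))


def read_centerlines(path: str | Path) -> dict[str, tuple[str, Centerline]]:
    """Read a centerline document: label -> (kind, Centerline)."""
    doc = json.loads(Path(path).read_text())
    out = {}
    for rec in doc["centerlines"]:
        out[rec["label"]] = (rec["kind"],
                             Centerline(np.asarray(rec["points"]), label=rec["label"]))
    return out


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class WedgeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tilt_min: float = -60.0
    tilt_max: float = 60.0
    increment: float = 3.0


class ObjectConfig(BaseModel):
    """One scene object: a filament, bundle or microtubule."""

    model_config = ConfigDict(extra="forbid")
    type: str  # 'filament' | 'bundle' | 'mt'
    start: list[float] | None = None
    centre: list[float] | None = None
    direction: list[float] = Field(default_factory=lambda: [1.0, 0.0, 0.0])
    length: float = 200.0
    repeat_class: str = "long"
    phase_offset: int = 0
    n_wide: int = 3
    n_high: int = 3
    lattice_constant: float = 12.1
    crosslink_period: float = 37.1
    positional_jitter: float = 0.0
    pf_number: int = 13
    lateral_rise: float = 0.92
    particle_frequency: float = 0.0
    label: str = ""


class RunConfig(BaseModel):
    """Validated configuration for a simulate run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    shape: list[int] = Field(default_factory=lambda: [200, 64, 64])  # (nx, ny, nz)
    voxel_size: float = 1.0
    noise_sd: float = 0.33
    wedge: WedgeConfig | None = None
    seed: int = 0
    objects: list[ObjectConfig] = Field(default_factory=list)
    thresholds: dict[str, float] = Field(default_factory=dict)
    log_level: str = "INFO"

    def model_post_init(self, _ctx) -> None:
        if self.voxel_size <= 0 or self.noise_sd < 0:
            raise ValidationError("voxel_size must be > 0 and noise_sd >= 0")
        if any(t <= 0 for t in self.thresholds.values()):
            raise ValidationError("all thresholds must be positive")


def load_config(path: str | Path) -> RunConfig:
    return RunConfig(**yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:12]


def plan_from_config(cfg: RunConfig, seed: int | None = None) -> ScenePlan:
    """Build a renderable :class:`ScenePlan` from a validated config."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    plan = ScenePlan(shape=tuple(cfg.shape), voxel_size=cfg.voxel_size,
                     wedge=MissingWedge(**cfg.wedge.model_dump()) if cfg.wedge else None,
                     noise_sd=cfg.noise_sd, seed=seed)
    centre_default = [s * cfg.voxel_size / 2 for s in cfg.shape]
    for i, obj in enumerate(cfg.objects):
        label = obj.label or f"{obj.type}{i}"
        if obj.type == "filament":
            start = obj.start or [20.0, centre_default[1], centre_default[2]]
            plan.filaments.append(make_filament(
                start, obj.direction, obj.length, obj.repeat_class,
                phase_offset=obj.phase_offset, label=label))
        elif obj.type == "bundle":
            centre = obj.centre or centre_default
            centre = [20.0, centre[1], centre[2]]
            plan.bundles.append(make_bundle(
                centre, obj.direction, obj.length, obj.n_wide, obj.n_high,
                lattice_constant=obj.lattice_constant,
                crosslink_period=obj.crosslink_period,
                positional_jitter=obj.positional_jitter,
                rng=rng, label=label))
        elif obj.type == "mt":
            start = obj.start or [20.0, centre_default[1], centre_default[2]]
            mt = make_mt(start, obj.direction, obj.length, label=label,
                         pf_number=obj.pf_number, lateral_rise=obj.lateral_rise)
            if obj.particle_frequency > 0:
                spacing = 8.2 / obj.particle_frequency
                for s in np.arange(15.0, obj.length - 15.0, spacing):
                    mt.particles.append(ParticleSpec(axial_position=float(s)))
            plan.mts.append(mt)
        else:
            raise ValidationError(f"unknown object type {obj.type!r}")
    return plan
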