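"""Run configuration: validated parameter blocks, hashing, seed derivation.

A run is described by one TOML (preferred; comments allowed) or JSON file
with optional blocks ``optics``, ``specimen``, ``stage``, ``plan``,
``acquisition``, ``stitching``, ``qc`` plus a global ``seed`` and an
``outdir``.  Unknown keys anywhere are rejected by name — silently ignored
typos in an experiment config are how scans get wasted.  The resolved
configuration is hashed (sha256 over its canonical JSON) and the hash is
recorded in every manifest so any artifact can be traced to the exact
configuration that produced it.

The single global seed is expanded into per-module seeds with
:func:`derive_seed` (sha256 of ``"<seed>:<role>"``, reduced below 2^31), so
partial re-runs of one stage reproduce exactly.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

from .hardware import StageState, piezo_model, stepper_model
from .planner import ScanPlan, plan_serpentine
from .specimen import OpticsModel, SpecimenVolume, make_nervenet_specimen

__all__ = ["RunConfig", "load_config", "derive_seed"]


@dataclass
class SpecimenConfig:
    extent_um: tuple[float, float, float] = (500.0, 500.0, 50.0)
    n_filaments: int = 40
    pitch_xy: float = 1.0
    pitch_z: float = 2.0
    background: float = 50.0
    filament_intensity: float = 1000.0
    surface_amplitude_um: float | None = None
    tilt: tuple[float, float] = (0.0, 0.0)


@dataclass
class StageConfig:
    kind: str = "piezo"
    nominal_um_per_unit: float | None = None
    variability_frac: float | None = None
    asymmetry_ratio: float | None = None
    coupling_error_frac: float | None = None
    load_g: float | None = None

    def build(self, axes: str = "xyz") -> StageState:
        overrides = {
            k: v
            for k, v in (
                ("nominal_um_per_unit", self.nominal_um_per_unit),
                ("variability_frac", self.variability_frac),
                ("asymmetry_ratio", self.asymmetry_ratio),
                ("coupling_error_frac", self.coupling_error_frac),
                ("load_g", self.load_g),
            )
            if v is not None
        }
        factory = stepper_model if self.kind == "stepper" else piezo_model
        start = {ax: 200.0 for ax in axes}  # park away from the hard stop
        return StageState({ax: factory(**overrides) for ax in axes}, position=start)


@dataclass
class PlanConfig:
    nx: int = 3
    ny: int = 2
    overlap_x: float = 0.25
    overlap_y: float = 0.30
    nz: int = 5
    dz_um: float = 2.0
    origin: tuple[float, float] = (200.0, 200.0)

    def build(self, optics: OpticsModel) -> ScanPlan:
        return plan_serpentine(
            self.nx,
            self.ny,
            optics.fov_um,
            self.overlap_x,
            self.overlap_y,
            self.origin,
            nz=self.nz,
            dz_um=self.dz_um,
        )


@dataclass
class AcquisitionConfig:
    z_start_um: float = 200.0
    enable_z_correction: bool = True
    settle_wait_ms: float = 500.0
    focus_metric: str = "normalized_gradient_variance"
    keep_stacks: bool = False


@dataclass
class StitchConfig:
    search_radius_px: float = 15.0
    min_confidence: float = 0.10
    blend_width_px: int = 16


@dataclass
class QCConfig:
    mtf_oversample: int = 4


_BLOCKS = {
    "optics": OpticsModel,
    "specimen": SpecimenConfig,
    "stage": StageConfig,
    "plan": PlanConfig,
    "acquisition": AcquisitionConfig,
    "stitching": StitchConfig,
    "qc": QCConfig,
}


@dataclass
class RunConfig:
    """A fully validated configuration for one scanning run."""

    optics: OpticsModel = field(default_factory=OpticsModel)
    specimen: SpecimenConfig = field(default_factory=SpecimenConfig)
    stage: StageConfig = field(default_factory=StageConfig)
    plan: PlanConfig = field(default_factory=PlanConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    stitching: StitchConfig = field(default_factory=StitchConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    seed: int = 0
    outdir: str = "scan_output"

    def resolved(self) -> dict:
        out = {name: asdict(getattr(self, name)) for name in _BLOCKS}
        out["seed"] = self.seed
        out["outdir"] = self.outdir
        return out

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def build_specimen(self, seed: int | None = None) -> SpecimenVolume:
        s = self.specimen
        return make_nervenet_specimen(
            tuple(s.extent_um),
            s.n_filaments,
            derive_seed(self.seed if seed is None else seed, "specimen"),
            pitch_xy=s.pitch_xy,
            pitch_z=s.pitch_z,
            background=s.background,
            filament_intensity=s.filament_intensity,
            surface_amplitude_um=s.surface_amplitude_um,
            tilt=tuple(s.tilt),
            origin=(
                self.plan.origin[0] - self.optics.fov_um,
                self.plan.origin[1] - self.optics.fov_um,
                self.acquisition.z_start_um - s.extent_um[2] / 2.0,
            ),
        )


def derive_seed(global_seed: int, role: str) -> int:
    """Stable per-module seed: sha256 of ``"<seed>:<role>"`` below 2^31."""
    digest = hashlib.sha256(f"{int(global_seed)}:{role}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _coerce(block_cls, payload: dict, path: str):
    valid = {f.name: f for f in fields(block_cls)}
    unknown = set(payload) - set(valid)
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) {sorted(unknown)} in [{path}]"
        )
    kwargs = {}
    for key, value in payload.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return block_cls(**kwargs)


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a run configuration from TOML or JSON.

    Missing blocks and keys take their defaults; unknown keys raise a
    ``ValueError`` naming the offending key and block.  ``data`` bypasses
    file reading (used by tests and programmatic callers).
    """
    if data is None:
        if path is None:
            raise ValueError("provide a path or a data dict")
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        if p.suffix.lower() == ".json":
            data = json.loads(p.read_text())
        else:
            with open(p, "rb") as fh:
                data = tomllib.load(fh)
    top_unknown = set(data) - set(_BLOCKS) - {"seed", "outdir"}
    if top_unknown:
        raise ValueError(f"unknown top-level configuration key(s) {sorted(top_unknown)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            if not isinstance(data[name], dict):
                raise ValueError(f"[{name}] must be a table/object")
            kwargs[name] = _coerce(cls, data[name], name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "outdir" in data:
        kwargs["outdir"] = str(data["outdir"])
    cfg = RunConfig(**kwargs)
    # instantiating the blocks runs their invariant checks (e.g. overlap < 1
    # via plan building); validate the plan geometry eagerly:
    cfg.plan.build(cfg.optics)
    return cfg
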