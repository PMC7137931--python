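"""Scan execution: Z-stacks, autofocus scoring, Z-correction, MIP.

Runs a :class:`~stagescan.planner.ScanPlan` against a stage and a camera.
The camera is anything callable as ``camera(position) -> 2D array`` — in
practice the :class:`VirtualCamera` below, which renders frames of a
synthetic specimen, but a real-camera adapter satisfies the same interface.

At every tile a Z-stack is acquired (one frame per planned focal plane,
each captured only after the configured post-move settle window — never
while the stage is in motion), per-plane focus scores are computed, and the
stack is collapsed to a maximum intensity projection.  Because the specimen
surface height varies across XY and open-loop Z travel is imperfect, the
best-focus plane drifts between tiles; the Z-correction feeds the offset of
the previous tile's best-focus plane from the stack centre forward as a
cumulative Z offset, keeping the surface inside every subsequent stack.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .hardware import StageState, settle_envelope
from .planner import ScanPlan, TilePlan, plan_zstack
from .specimen import OpticsModel, SpecimenVolume, render_frame, write_stack

__all__ = [
    "VirtualCamera",
    "TileRecord",
    "focus_score",
    "FOCUS_METRICS",
    "max_intensity_projection",
    "run_tile",
    "z_correct",
    "run_scan",
]


class VirtualCamera:
    """Render frames of a synthetic specimen at the stage's actual position.

    Noise draws come from a private generator seeded once, so a scan is
    reproducible for a fixed seed and identical call order.
    """

    def __init__(self, volume: SpecimenVolume, optics: OpticsModel, seed: int = 0):
        self.volume = volume
        self.optics = optics
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)
        self._cache = None  # reused across the frames of one Z-stack

    def __call__(self, position: dict[str, float]) -> np.ndarray:
        from .specimen import _PlaneCache

        key = (
            id(self.volume),
            float(position["x"]),
            float(position["y"]),
            self.optics.fov_px,
            self.optics.pixel_um,
        )
        if self._cache is None or self._cache.key != key:
            self._cache = _PlaneCache(
                self.volume, position["x"], position["y"], self.optics
            )
        return render_frame(
            self.volume, position, self.optics, self._rng, cache=self._cache
        )


# ---------------------------------------------------------------------------
# autofocus metric
# ---------------------------------------------------------------------------

def _normalized_gradient_variance(image: np.ndarray) -> float:
    img = np.asarray(image, dtype=np.float64)
    gx = ndimage.sobel(img, axis=1)
    gy = ndimage.sobel(img, axis=0)
    g = np.hypot(gx, gy)
    mean = g.mean()
    if mean <= 0:
        return 0.0
    return float(g.var() / mean**2)


def _gradient_variance(image: np.ndarray) -> float:
    img = np.asarray(image, dtype=np.float64)
    g = np.hypot(ndimage.sobel(img, axis=1), ndimage.sobel(img, axis=0))
    return float(g.var())


#: Pluggable focus metrics.  All are >= 0, zero on constant images, and
#: invariant to adding a constant offset to every pixel.
FOCUS_METRICS = {
    "normalized_gradient_variance": _normalized_gradient_variance,
    "gradient_variance": _gradient_variance,
}

DEFAULT_FOCUS_METRIC = "normalized_gradient_variance"


def focus_score(image: np.ndarray, metric: str = DEFAULT_FOCUS_METRIC) -> float:
    """Sharpness score of a frame (higher = sharper).

    The default metric is the variance of the Sobel gradient magnitude
    normalized by its squared mean (Tenengrad family): offset- and
    scale-invariant, zero for constant images.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    try:
        fn = FOCUS_METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown focus metric {metric!r}; available: {sorted(FOCUS_METRICS)}"
        ) from None
    return fn(img)


def max_intensity_projection(stack: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Per-pixel maximum across the planes of a Z-stack."""
    planes = [np.asarray(p) for p in stack]
    if len(planes) == 0:
        raise ValueError("stack must contain at least one plane")
    shape = planes[0].shape
    for k, p in enumerate(planes):
        if p.shape != shape:
            raise ValueError(f"plane {k} shape {p.shape} != plane 0 shape {shape}")
    return np.maximum.reduce(planes)


# ---------------------------------------------------------------------------
# tiles
# ---------------------------------------------------------------------------

@dataclass
class TileRecord:
    """Acquisition results for one tile."""

    i: int
    j: int
    nominal_xy_um: tuple[float, float]
    achieved_xy_um: tuple[float, float]
    z_targets_um: list[float]
    achieved_z_um: list[float]
    focus_scores: list[float]
    best_index: int
    z_correction_um: float          # cumulative offset applied before this tile
    stack: np.ndarray | None = None
    mip: np.ndarray | None = None
    stack_path: str | None = None
    mip_path: str | None = None
    flags: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "i": self.i,
            "j": self.j,
            "nominal_xy_um": list(self.nominal_xy_um),
            "achieved_xy_um": list(self.achieved_xy_um),
            "z_targets_um": list(self.z_targets_um),
            "achieved_z_um": list(self.achieved_z_um),
            "focus_scores": list(self.focus_scores),
            "best_index": self.best_index,
            "z_correction_um": self.z_correction_um,
            "stack_path": self.stack_path,
            "mip_path": self.mip_path,
            "flags": list(self.flags),
        }


def run_tile(
    stage: StageState,
    camera,
    tile: TilePlan,
    z_targets_um: np.ndarray,
    z_correction_um: float = 0.0,
    *,
    settle_wait_ms: float = 500.0,
    settle_threshold_um: float = 0.05,
    focus_metric: str = DEFAULT_FOCUS_METRIC,
    rng=None,
) -> TileRecord:
    """Acquire one tile's Z-stack at the stage's current XY position.

    The stage is stepped through ``z_targets_um + z_correction_um``; after
    every move the simulation waits ``settle_wait_ms`` before triggering the
    camera (acquisition never happens during motion), and a flag is raised
    if the configured wait leaves the residual settle amplitude above
    ``settle_threshold_um``.  Ties in the focus scores break toward the
    lower plane index.
    """
    flags: list[str] = []
    z_model = stage.actuators["z"]
    if settle_envelope(z_model, settle_wait_ms) > settle_threshold_um:
        flags.append("settle_wait_too_short")

    frames: list[np.ndarray] = []
    scores: list[float] = []
    achieved_z: list[float] = []
    targets = [float(z) + float(z_correction_um) for z in np.atleast_1d(z_targets_um)]
    for z in targets:
        stage.move_to({"z": z}, rng_seed=rng)
        achieved_z.append(stage.position["z"])
        try:
            frame = camera(dict(stage.position))
        except Exception as exc:
            raise RuntimeError(
                f"camera failed at tile ({tile.i}, {tile.j}), z={z:.2f} um: {exc}"
            ) from exc
        frames.append(frame)
        scores.append(focus_score(frame, focus_metric))

    stack = np.stack(frames)
    best = int(np.argmax(scores))  # argmax ties -> lowest index
    return TileRecord(
        i=tile.i,
        j=tile.j,
        nominal_xy_um=(tile.x_um, tile.y_um),
        achieved_xy_um=(stage.position["x"], stage.position["y"]),
        z_targets_um=targets,
        achieved_z_um=achieved_z,
        focus_scores=scores,
        best_index=best,
        z_correction_um=float(z_correction_um),
        stack=stack,
        mip=max_intensity_projection(stack),
        flags=flags,
    )


def z_correct(previous: TileRecord, dz_um: float, nz: int) -> float:
    """Incremental Z offset that recentres the previous best-focus plane.

    Returns ``(best_index - (nz - 1) / 2) * dz_um``: if the sharpest plane
    sat above the stack centre (deeper), the next stack starts deeper by the
    same amount.  A featureless previous tile (all scores zero or equal)
    contributes no correction, with a logged warning, so the running offset
    is carried over unchanged.
    """
    scores = np.asarray(previous.focus_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("previous tile has no focus scores")
    if scores.max() <= 0 or np.ptp(scores) == 0:
        warnings.warn(
            f"tile ({previous.i}, {previous.j}) featureless: no usable focus "
            "signal, Z-correction carried over unchanged",
            stacklevel=2,
        )
        return 0.0
    return (previous.best_index - (nz - 1) / 2.0) * float(dz_um)


# ---------------------------------------------------------------------------
# whole-scan execution
# ---------------------------------------------------------------------------

def _config_hash(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_scan(
    plan: ScanPlan,
    stage: StageState,
    camera,
    *,
    z_start_um: float = 0.0,
    enable_z_correction: bool = True,
    settle_wait_ms: float = 500.0,
    focus_metric: str = DEFAULT_FOCUS_METRIC,
    keep_stacks: bool = True,
    outdir: str | Path | None = None,
    rng=None,
    seed_info: dict | None = None,
) -> tuple[list[TileRecord], dict]:
    """Execute a full serpentine scan; returns (tile records, manifest).

    Tiles are visited in the plan's serpentine order.  Per tile: move XY,
    acquire the Z-stack (shifted by the running Z-correction offset), score
    focus, project.  With ``outdir`` set, stacks are written as multi-page
    TIFF (``tile_jYY_iXX.tif``), MIPs as single-page TIFF, and the manifest
    as ``manifest.json``.  If a tile fails mid-scan the manifest is still
    written, with the completed tiles and a failure marker, so the scan is
    resumable.  ``keep_stacks=False`` drops raw stacks from memory after
    projection (the frame count is still accounted in the manifest).
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "plan": json.loads(plan.to_json()),
        "z_start_um": z_start_um,
        "enable_z_correction": bool(enable_z_correction),
        "settle_wait_ms": settle_wait_ms,
        "focus_metric": focus_metric,
        "seed_info": seed_info or {},
        "tiles": [],
        "n_frames": 0,
        "n_mips": 0,
        "status": "running",
    }
    manifest["config_hash"] = _config_hash(
        {k: manifest[k] for k in ("plan", "z_start_um", "settle_wait_ms", "focus_metric")}
    )

    records: list[TileRecord] = []
    z_offset = 0.0
    base_targets = plan_zstack(plan.nz, plan.dz_um, z_start_um)
    try:
        for tile in plan.tiles:
            stage.move_to({"x": tile.x_um, "y": tile.y_um}, rng_seed=rng)
            record = run_tile(
                stage,
                camera,
                tile,
                base_targets,
                z_correction_um=z_offset,
                settle_wait_ms=settle_wait_ms,
                focus_metric=focus_metric,
                rng=rng,
            )
            if outdir is not None:
                stem = f"tile_j{tile.j:02d}_i{tile.i:02d}"
                record.stack_path = str(outdir / f"{stem}.tif")
                record.mip_path = str(outdir / f"{stem}_mip.tif")
                write_stack(record.stack_path, record.stack)
                write_stack(record.mip_path, record.mip)
            if enable_z_correction:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    z_offset += z_correct(record, plan.dz_um, plan.nz)
            manifest["tiles"].append(record.summary())
            manifest["n_frames"] += len(record.focus_scores)
            manifest["n_mips"] += 1
            if not keep_stacks:
                record.stack = None
            records.append(record)
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure"] = {
            "completed_tiles": len(records),
            "error": str(exc),
        }
        if outdir is not None:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["status"] = "complete"
    if outdir is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return records, manifest
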