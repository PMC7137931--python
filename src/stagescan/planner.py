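"""Serpentine scan planning and stage-command generation.

The acquisition treats the sample as a 2D array of fields of view: the stage
steps along X ``nx`` times, steps once in Y, then returns along X in the
opposite direction (boustrophedon traversal — consecutive tiles never differ
in both X and Y, so path length is minimal among row-major orderings).  Each
tile carries a Z-stack sub-plan.  Adjacent tiles overlap by a configured
fraction of the field of view: ``pitch = fov * (1 - overlap)``, which
reproduces the working overlaps of 25 % (X) / 30 % (Y) for the piezo stage
at 20x, and 10 % for the stepper stage.

For the stepper stage the plan can be emitted as a gcode program (absolute
positioning, millimetre units) for an Arduino-hosted interpreter, and parsed
back for verification.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .hardware import Calibration, round_half_away, TRAVEL_UM

__all__ = [
    "TilePlan",
    "ScanPlan",
    "GcodeProgram",
    "plan_serpentine",
    "plan_zstack",
    "to_gcode",
    "parse_gcode",
    "distance_to_commands",
]


@dataclass(frozen=True)
class TilePlan:
    """One planned field of view: grid index, nominal stage XY (um)."""

    i: int           # column index (X)
    j: int           # row index (Y)
    x_um: float
    y_um: float
    reverse_row: bool  # True on rows scanned in the -X direction


@dataclass
class ScanPlan:
    """An ordered serpentine grid of nominal stage targets."""

    nx: int
    ny: int
    fov_um: tuple[float, float]
    overlap_x: float
    overlap_y: float
    origin: tuple[float, float]
    tiles: list[TilePlan]
    nz: int = 1
    dz_um: float = 1.0

    @property
    def pitch_um(self) -> tuple[float, float]:
        return (
            self.fov_um[0] * (1.0 - self.overlap_x),
            self.fov_um[1] * (1.0 - self.overlap_y),
        )

    def nominal_overlap(self) -> tuple[float, float]:
        """Overlap fractions measured back from nominal positions:
        (fov - pitch) / fov per axis."""
        px, py = self.pitch_um
        return (
            (self.fov_um[0] - px) / self.fov_um[0],
            (self.fov_um[1] - py) / self.fov_um[1],
        )

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScanPlan":
        payload = json.loads(text)
        payload["tiles"] = [TilePlan(**t) for t in payload["tiles"]]
        payload["fov_um"] = tuple(payload["fov_um"])
        payload["origin"] = tuple(payload["origin"])
        return cls(**payload)


def plan_serpentine(
    nx: int,
    ny: int,
    fov_um: float | tuple[float, float],
    overlap_x: float,
    overlap_y: float,
    origin: tuple[float, float] = (0.0, 0.0),
    *,
    nz: int = 1,
    dz_um: float = 1.0,
) -> ScanPlan:
    """Build a serpentine XY tile plan.

    Tile (i, j) sits at ``origin + (i * pitch_x, j * pitch_y)``; the first
    row (j = 0) is visited in +X order and the direction alternates on every
    subsequent row.  Overlaps are fractions of the FOV in [0, 1).
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if not (0.0 <= overlap_x < 1.0 and 0.0 <= overlap_y < 1.0):
        raise ValueError("overlaps must be in [0, 1)")
    if np.isscalar(fov_um):
        fov = (float(fov_um), float(fov_um))
    else:
        fov = (float(fov_um[0]), float(fov_um[1]))
    if fov[0] <= 0 or fov[1] <= 0:
        raise ValueError("fov_um must be > 0")
    if nz < 1:
        raise ValueError("nz must be >= 1")

    pitch_x = fov[0] * (1.0 - overlap_x)
    pitch_y = fov[1] * (1.0 - overlap_y)
    tiles: list[TilePlan] = []
    for j in range(ny):
        reverse = bool(j % 2)
        cols = range(nx - 1, -1, -1) if reverse else range(nx)
        for i in cols:
            tiles.append(
                TilePlan(
                    i=i,
                    j=j,
                    x_um=origin[0] + i * pitch_x,
                    y_um=origin[1] + j * pitch_y,
                    reverse_row=reverse,
                )
            )
    return ScanPlan(nx, ny, fov, overlap_x, overlap_y, tuple(origin), tiles, nz, dz_um)


def plan_zstack(
    nz: int, dz_um: float, z_start: float, reverse: bool = False
) -> np.ndarray:
    """Ordered Z targets (um): ``nz`` planes spaced ``dz_um`` from z_start.

    ``reverse=True`` flips the visiting order only; the set of planes is
    unchanged.
    """
    if nz < 1:
        raise ValueError("nz must be >= 1")
    targets = z_start + np.arange(nz) * float(dz_um)
    return targets[::-1].copy() if reverse else targets


# ---------------------------------------------------------------------------
# gcode emission / parsing
# ---------------------------------------------------------------------------

@dataclass
class GcodeProgram:
    """A plain-text gcode program (absolute positioning, mm units)."""

    lines: list[str]
    units: str = "mm"
    positioning: str = "absolute"

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.text)


_GCODE_MOVE = re.compile(r"^G0*[01]\b")
_GCODE_COORD = re.compile(r"([XYZ])(-?\d+(?:\.\d+)?)")


def to_gcode(plan: ScanPlan) -> GcodeProgram:
    """Emit a ScanPlan as an absolute-positioning gcode program.

    Preamble sets millimetre units (G21) and absolute positioning (G90);
    each tile becomes one rapid move (G0) with coordinates printed to
    0.0001 mm = 0.1 um, so a parse round-trip reproduces the nominal
    positions to that precision.  All coordinates must lie within the
    13 mm stage travel.
    """
    lines = [
        "; serpentine tile scan",
        "G21 ; units: mm",
        "G90 ; absolute positioning",
    ]
    for tile in plan.tiles:
        x_mm = tile.x_um / 1000.0
        y_mm = tile.y_um / 1000.0
        if not (0.0 <= tile.x_um <= TRAVEL_UM and 0.0 <= tile.y_um <= TRAVEL_UM):
            raise ValueError(
                f"tile ({tile.i}, {tile.j}) at ({tile.x_um:.1f}, {tile.y_um:.1f}) um "
                f"outside the [0, {TRAVEL_UM:.0f}] um travel range"
            )
        lines.append(f"G0 X{x_mm:.4f} Y{y_mm:.4f}")
    return GcodeProgram(lines)


def parse_gcode(program: GcodeProgram | str) -> list[dict[str, float]]:
    """Parse a gcode program into a list of absolute targets in um.

    Only G0/G1 moves are interpreted; unknown words on a move line raise.
    Comment lines (';' or parenthesised) and mode-setting lines are skipped.
    """
    text = program.text if isinstance(program, GcodeProgram) else program
    targets: list[dict[str, float]] = []
    current: dict[str, float] = {}
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line or line.startswith("("):
            continue
        if not _GCODE_MOVE.match(line):
            continue
        words = _GCODE_COORD.findall(line)
        leftover = _GCODE_COORD.sub("", _GCODE_MOVE.sub("", line)).strip()
        if leftover:
            raise ValueError(f"unparseable gcode move line: {raw!r}")
        current = dict(current)
        for axis, value in words:
            current[axis.lower()] = float(value) * 1000.0  # mm -> um
        targets.append(dict(current))
    return targets


def distance_to_commands(
    distance_um: float,
    um_per_unit: float | None = None,
    *,
    calibration: Calibration | None = None,
    axis: str | None = None,
) -> int:
    """Convert a physical distance to an integer command-unit count.

    Either pass the conversion factor directly (``um_per_unit``) or a
    :class:`~stagescan.hardware.Calibration` table plus the axis, in which
    case the direction (up for positive distances, down for negative) picks
    the calibrated slope.  Rounding is to the nearest integer, halves away
    from zero.
    """
    if um_per_unit is None:
        if calibration is None or axis is None:
            raise ValueError("provide um_per_unit, or calibration together with axis")
        direction = "up" if distance_um >= 0 else "down"
        um_per_unit = calibration.lookup(axis, direction)  # raises naming axis/direction
    if um_per_unit <= 0:
        raise ValueError("um_per_unit must be > 0")
    return round_half_away(distance_um / um_per_unit)
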