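"""Virtual motion-control hardware.

Two actuator families drive the simulated 4-axis stage:

* **Piezoelectric inertial actuators** — open-loop friction drives whose real
  displacement per commanded "step size" unit depends on load, direction and
  drive settings.  The per-actuation distance is stochastic (bounded relative
  variability) and asymmetric: mean up-travel exceeds mean down-travel.
* **Micrometer-coupled stepper motors** — 500 um per revolution, 200 full
  steps per revolution, 1/16 microstepping, hence 2.5 um per full step and
  156.25 nm per microstep.  Motion is deterministic up to an optional fixed
  coupling-error fraction emulating mechanical misalignment.

Both stage types offer 13 mm (13000 um) of travel per axis.  Axis positions
are expressed in um within [0, travel_um]; moves that would exceed the travel
range are clamped at the hard stop and flagged in the command log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TRAVEL_UM",
    "STEPPER_UM_PER_FULL_STEP",
    "STEPPER_UM_PER_MICROSTEP",
    "MICROSTEPS_PER_FULL_STEP",
    "ActuatorModel",
    "MoveRecord",
    "StageState",
    "Calibration",
    "actuate",
    "settle_profile",
    "settle_envelope",
]

TRAVEL_UM = 13_000.0

# 500 um per micrometer revolution / 200 full steps per revolution
STEPPER_UM_PER_FULL_STEP = 500.0 / 200.0          # = 2.5 um
MICROSTEPS_PER_FULL_STEP = 16
STEPPER_UM_PER_MICROSTEP = STEPPER_UM_PER_FULL_STEP / MICROSTEPS_PER_FULL_STEP  # = 0.15625 um


@dataclass(frozen=True)
class ActuatorModel:
    """Parametric model of one motion axis.

    Parameters
    ----------
    kind:
        ``"piezo"`` or ``"stepper"``.
    nominal_um_per_unit:
        Mean displacement (um) per command unit in the *up* (+) direction at
        the calibrated load.  The piezo default is 0.02 um (the actuators'
        typical 20 nm step); the stepper default is one 1/16 microstep.
    variability_frac:
        Maximum relative deviation of a single actuation from its directional
        mean; the draw is uniform on ±variability_frac, so the bound is hard.
    asymmetry_ratio:
        mean(|up-travel|) / mean(|down-travel|).  Implemented as a divisor on
        the downward mean; 1.0 disables the asymmetry.
    coupling_error_frac:
        Stepper-only fixed relative scale error (mimics imperfect motor ↔
        micrometer coupling); 0 by default.
    load_g:
        Attached mass in grams.  Metadata only: the model is calibrated per
        load rather than deriving displacement from mass.
    settle_amp_um / settle_tau_ms / settle_freq_hz:
        Damped-oscillation residual after a move (see :func:`settle_profile`).
    """

    kind: str = "piezo"
    nominal_um_per_unit: float = 0.02
    variability_frac: float = 0.20
    asymmetry_ratio: float = 1.15
    coupling_error_frac: float = 0.0
    load_g: float = 335.0
    travel_um: float = TRAVEL_UM
    settle_amp_um: float = 0.5
    settle_tau_ms: float = 60.0
    settle_freq_hz: float = 40.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("piezo", "stepper"):
            raise ValueError(f"unknown actuator kind {self.kind!r}")
        if self.nominal_um_per_unit <= 0:
            raise ValueError("nominal_um_per_unit must be > 0")
        if not 0.0 <= self.variability_frac < 1.0:
            raise ValueError("variability_frac must be in [0, 1)")
        if self.asymmetry_ratio <= 0:
            raise ValueError("asymmetry_ratio must be > 0")
        if self.travel_um <= 0:
            raise ValueError("travel_um must be > 0")

    def mean_um_per_unit(self, direction: int) -> float:
        """Directional mean displacement per command unit (always > 0)."""
        if direction >= 0:
            return self.nominal_um_per_unit
        return self.nominal_um_per_unit / self.asymmetry_ratio


def stepper_model(**overrides) -> ActuatorModel:
    """Ideal microstepping-stepper axis (deterministic, symmetric)."""
    defaults = dict(
        kind="stepper",
        nominal_um_per_unit=STEPPER_UM_PER_MICROSTEP,
        variability_frac=0.0,
        asymmetry_ratio=1.0,
        load_g=0.0,
        settle_amp_um=1.0,
        settle_tau_ms=70.0,
        settle_freq_hz=50.0,
    )
    defaults.update(overrides)
    return ActuatorModel(**defaults)


def piezo_model(**overrides) -> ActuatorModel:
    """Default piezo inertial-actuator axis (±20 % variability, up > down)."""
    return replace(ActuatorModel(), **overrides) if overrides else ActuatorModel()


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def actuate(model: ActuatorModel, command_units: float, rng_seed=None) -> float:
    """Simulate one actuation command and return the signed displacement (um).

    Stepper axes move exactly ``units × nominal`` (scaled by the fixed
    coupling error if configured).  Piezo axes draw a single displacement
    ``units × directional-mean × (1 + U(−v, +v))`` so that the relative
    deviation from the directional mean never exceeds ``variability_frac``.
    """
    units = float(command_units)
    if units == 0.0:
        return 0.0
    sign = 1.0 if units > 0 else -1.0
    if model.kind == "stepper":
        return units * model.nominal_um_per_unit * (1.0 + model.coupling_error_frac)
    mean = model.mean_um_per_unit(int(sign))
    rng = _as_rng(rng_seed)
    frac = rng.uniform(-model.variability_frac, model.variability_frac)
    return units * mean * (1.0 + frac)


def settle_profile(model: ActuatorModel, t_ms: float | np.ndarray) -> np.ndarray | float:
    """Residual displacement (um) at time ``t_ms`` after motion ceases.

    Modelled as an exponentially damped sinusoid
    ``A · exp(−t/τ) · cos(2π f t)``; images are only acquired once the
    envelope has decayed below the acquisition threshold.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_ms must be >= 0")
    out = (
        model.settle_amp_um
        * np.exp(-t / model.settle_tau_ms)
        * np.cos(2.0 * math.pi * model.settle_freq_hz * t / 1000.0)
    )
    return float(out) if np.isscalar(t_ms) else out


def settle_envelope(model: ActuatorModel, t_ms: float | np.ndarray) -> np.ndarray | float:
    """Decay envelope ``A · exp(−t/τ)`` of :func:`settle_profile`."""
    t = np.asarray(t_ms, dtype=float)
    out = model.settle_amp_um * np.exp(-t / model.settle_tau_ms)
    return float(out) if np.isscalar(t_ms) else out


@dataclass
class MoveRecord:
    """One issued command: axis, units, what was asked for and what happened."""

    axis: str
    command_units: float
    requested_um: float
    achieved_um: float
    clamped: bool


class Calibration:
    """Per-axis, per-direction command-unit calibration table.

    Maps ``(axis, direction)`` — direction ``"up"`` (+) or ``"down"`` (−) —
    to a measured um-per-unit slope, as produced by
    :func:`stagescan.qc.calibrate_steps`.
    """

    def __init__(self, um_per_unit: dict[tuple[str, str], float]):
        self._table = dict(um_per_unit)

    def lookup(self, axis: str, direction: str) -> float:
        try:
            return self._table[(axis, direction)]
        except KeyError:
            raise KeyError(
                f"no calibration for axis {axis!r}, direction {direction!r}"
            ) from None

    def __contains__(self, key) -> bool:
        return key in self._table

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(self._table)


class StageState:
    """Current position and command history of a multi-axis stage.

    Axes are named (``x, y, z`` and optionally the micromanipulator approach
    axis ``a``); each carries its own :class:`ActuatorModel`.  All positions
    are um within ``[0, travel_um]``.
    """

    def __init__(
        self,
        actuators: dict[str, ActuatorModel],
        position: dict[str, float] | None = None,
    ):
        self.actuators = dict(actuators)
        self.position = {ax: 0.0 for ax in self.actuators}
        if position:
            for ax, value in position.items():
                self._check_in_travel(ax, value)
                self.position[ax] = float(value)
        self.log: list[MoveRecord] = []

    # -- helpers -----------------------------------------------------------
    def _check_in_travel(self, axis: str, value: float) -> None:
        model = self.actuators[axis]
        if not 0.0 <= value <= model.travel_um:
            raise ValueError(
                f"target {value:.3f} um on axis {axis!r} outside travel "
                f"[0, {model.travel_um:.0f}] um"
            )

    # -- commands ----------------------------------------------------------
    def move(self, axis: str, command_units: float, rng_seed=None) -> float:
        """Issue a raw command on one axis; returns achieved displacement (um).

        The simulated displacement is clamped at the travel hard stops; a
        clamped move is flagged in the command log rather than raising, which
        mirrors how the physical stage behaves.
        """
        model = self.actuators[axis]
        displacement = actuate(model, command_units, rng_seed)
        start = self.position[axis]
        unclamped = start + displacement
        end = min(max(unclamped, 0.0), model.travel_um)
        clamped = end != unclamped
        self.position[axis] = end
        self.log.append(
            MoveRecord(axis, float(command_units), displacement, end - start, clamped)
        )
        return end - start

    def move_to(
        self,
        target: dict[str, float],
        rng_seed=None,
        calibration: Calibration | None = None,
    ) -> dict[str, float]:
        """Drive each axis toward ``target`` (um) and return achieved position.

        Command units per axis are the rounded ratio of the remaining distance
        to the calibrated um-per-unit for that axis and direction.  Without an
        explicit :class:`Calibration` the actuator model's own directional
        mean is used (a perfectly calibrated open-loop move), so the residual
        error is quantization for steppers and the bounded per-actuation
        variability for piezos.  Unreachable targets raise before any motion.
        """
        rng = _as_rng(rng_seed)
        for axis, value in target.items():
            if axis not in self.actuators:
                raise KeyError(f"unknown axis {axis!r}")
            self._check_in_travel(axis, value)
        for axis, value in target.items():
            delta = float(value) - self.position[axis]
            if delta == 0.0:
                continue
            direction = "up" if delta > 0 else "down"
            model = self.actuators[axis]
            if calibration is not None and (axis, direction) in calibration:
                upu = calibration.lookup(axis, direction)
            else:
                upu = model.mean_um_per_unit(1 if delta > 0 else -1)
            units = round_half_away(delta / upu)
            if units != 0:
                self.move(axis, units, rng)
        return dict(self.position)

    # -- accounting --------------------------------------------------------
    def net_travel(self, axis: str) -> float:
        """Sum of achieved per-move displacements on one axis."""
        return sum(rec.achieved_um for rec in self.log if rec.axis == axis)

    def log_rows(self) -> list[dict]:
        """Command log as plain dicts (CSV-ready)."""
        return [
            {
                "axis": r.axis,
                "command_units": r.command_units,
                "requested_um": r.requested_um,
                "achieved_um": r.achieved_um,
                "clamped": r.clamped,
            }
            for r in self.log
        ]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (documented convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def make_stage(kind: str = "stepper", axes: str = "xyz", **model_overrides) -> StageState:
    """Convenience constructor: identical actuators on every requested axis."""
    factory = stepper_model if kind == "stepper" else piezo_model
    return StageState({ax: factory(**model_overrides) for ax in axes})
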