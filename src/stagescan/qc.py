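"""Optical and mechanical quality control: the validation mathematics.

Covers the resolution arithmetic for USAF-1951 targets, diffraction limits,
slant-edge MTF estimation (the basis of the ISO 12233 e-SFR method),
registration-based displacement and drift measurement, per-axis actuator
step calibration statistics, and illumination-uniformity reporting.

USAF-1951 arithmetic
--------------------
A group/element pair indexes a three-bar pattern with

    RES_LP(G, E) = 2 ** (G + (E - 1) / 6)     line pairs per mm
    RES_CC       = 1000 / RES_LP              um per line pair

Diffraction limits for an objective of numerical aperture NA at emission
wavelength lambda:

    Abbe     d = lambda / (2 NA)
    Rayleigh d = 1.22 * lambda / (2 NA)

At NA = 0.5 the Abbe limit equals the wavelength (e.g. 530 nm) and the
Rayleigh limit is 1.22x that (647 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .hardware import Calibration
from .registration import phase_correlate

__all__ = [
    "res_lp",
    "res_cc",
    "abbe_limit",
    "rayleigh_limit",
    "MTFCurve",
    "slant_edge_mtf",
    "DisplacementMeasurement",
    "measure_displacement",
    "drift_track",
    "CalibrationRecord",
    "CalibrationResult",
    "calibrate_steps",
    "illumination_uniformity",
]


# ---------------------------------------------------------------------------
# closed-form resolution arithmetic
# ---------------------------------------------------------------------------

def res_lp(group: int, element: int) -> float:
    """Line pairs per mm of a USAF-1951 group/element: 2**(G + (E-1)/6)."""
    if not 1 <= int(element) <= 6:
        raise ValueError(f"element must be in 1..6, got {element}")
    return float(2.0 ** (group + (element - 1) / 6.0))

def res_cc(lp_per_mm: float) -> float:
    """Line-pair spacing in um: 1000 / RES_LP."""
    if lp_per_mm <= 0:
        raise ValueError("lp_per_mm must be > 0")
    return 1000.0 / lp_per_mm

def abbe_limit(wavelength_nm: float, na: float) -> float:
    """Abbe diffraction limit d = lambda / (2 NA), in nm."""
    if na <= 0:
        raise ValueError("na must be > 0")
    return wavelength_nm / (2.0 * na)

def rayleigh_limit(wavelength_nm: float, na: float) -> float:
    """Rayleigh criterion: 1.22 x the Abbe limit, in nm."""
    return 1.22 * abbe_limit(wavelength_nm, na)


# ---------------------------------------------------------------------------
# slant-edge MTF
# ---------------------------------------------------------------------------

@dataclass
class MTFCurve:
    """Modulation transfer function sampled on a frequency axis.

    ``frequency`` is in cycles/pixel (reported up to Nyquist, 0.5),
    ``contrast`` is normalized so that MTF(0) = 1, ``edge_angle_deg`` is the
    detected edge tilt off the image axis, ``oversample`` the ESF
    super-sampling factor used.
    """

    frequency: np.ndarray
    contrast: np.ndarray
    edge_angle_deg: float
    oversample: int

    def at(self, freq: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the curve."""
        return np.interp(freq, self.frequency, self.contrast)


def _edge_positions(img: np.ndarray) -> np.ndarray:
    """Sub-pixel edge column per row via derivative-magnitude centroid."""
    grad = np.gradient(img, axis=1)
    mag = np.abs(grad)
    weight = mag.sum(axis=1)
    cols = np.arange(img.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = (mag * cols).sum(axis=1) / weight
    return pos, weight


def slant_edge_mtf(edge_image: np.ndarray, oversample: int = 4) -> MTFCurve:
    """Estimate the MTF from an image of a single slanted step edge.

    Pipeline (fixed recipe): detect edge orientation; locate the edge per
    row by the centroid of the derivative magnitude; fit a straight line to
    get the edge angle (must be 2-15 degrees off axis, the usable range for
    phase diversity); project every pixel onto the edge-normal axis; bin
    into an ``oversample``-fold super-sampled edge-spread function (empty
    bins interpolated); differentiate to the line-spread function; apply a
    Hamming window centred on the LSF; take the discrete Fourier magnitude;
    correct for the finite-difference derivative and bin-averaging transfer
    functions; normalize to 1 at zero frequency.  Frequencies are reported
    up to 0.5 cycles/pixel.
    """
    img = np.asarray(edge_image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("edge image must be 2D, at least 16x16")
    # near-horizontal edges are handled by transposing to near-vertical
    gx = np.abs(np.gradient(img, axis=1)).sum()
    gy = np.abs(np.gradient(img, axis=0)).sum()
    if gy > gx:
        img = img.T
    if np.ptp(img) <= 0:
        raise ValueError("no detectable edge: image is constant")

    pos, weight = _edge_positions(img)
    good = weight > 0.05 * weight.max()
    if good.sum() < 8:
        raise ValueError("no detectable edge: too few rows with gradient signal")
    rows = np.arange(img.shape[0])[good]
    slope, intercept = np.polyfit(rows, pos[good], 1)
    angle_deg = float(np.degrees(np.arctan(slope)))
    if not 2.0 <= abs(angle_deg) <= 15.0:
        raise ValueError(
            f"edge angle {angle_deg:.2f} deg off axis is outside the usable "
            "2-15 degree range for slant-edge analysis"
        )

    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cos_t = np.cos(np.arctan(slope))
    d = (xx - (slope * yy + intercept)) * cos_t  # edge-normal distance, px

    # keep a symmetric central range fully covered by every row
    r_max = np.floor(min(abs(d[:, 0].max()), abs(d[:, -1].min())) - 1.0)
    if r_max < 4:
        raise ValueError("edge too close to the image border for ESF extraction")
    sel = np.abs(d) <= r_max
    delta = 1.0 / oversample
    bins = np.round(d[sel] / delta).astype(int)
    bmin, bmax = bins.min(), bins.max()
    idx = bins - bmin
    counts = np.bincount(idx, minlength=bmax - bmin + 1)
    sums = np.bincount(idx, weights=img[sel], minlength=bmax - bmin + 1)
    esf = np.full(counts.shape, np.nan)
    nz = counts > 0
    esf[nz] = sums[nz] / counts[nz]
    if (~nz).any():  # interpolate empty bins
        x_all = np.arange(esf.size)
        esf[~nz] = np.interp(x_all[~nz], x_all[nz], esf[nz])

    lsf = np.gradient(esf, delta)
    centroid = (np.abs(lsf) * np.arange(lsf.size)).sum() / np.abs(lsf).sum()
    half = int(min(centroid, lsf.size - 1 - centroid))
    lo, hi = int(round(centroid)) - half, int(round(centroid)) + half + 1
    lsf = lsf[lo:hi]
    lsf = lsf * np.hamming(lsf.size)

    spectrum = np.abs(np.fft.rfft(lsf))
    freqs = np.fft.rfftfreq(lsf.size, d=delta)
    # corrections: central-difference derivative and bin-average box filter
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.sinc(2.0 * freqs * delta) * np.sinc(freqs * delta)
    corr[corr < 0.2] = 1.0  # do not amplify far beyond the correction's validity
    mtf = spectrum / np.maximum(corr, 1e-9)
    if mtf[0] <= 0:
        raise ValueError("degenerate edge: zero total contrast")
    mtf = mtf / mtf[0]
    keep = freqs <= 0.5
    return MTFCurve(freqs[keep], mtf[keep], angle_deg, oversample)


# ---------------------------------------------------------------------------
# displacement and drift from image registration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisplacementMeasurement:
    """A registration-based displacement: um vector plus confidence flag."""

    dx_um: float
    dy_um: float
    dx_px: float
    dy_px: float
    confidence: float
    flagged: bool

    @property
    def magnitude_um(self) -> float:
        return float(np.hypot(self.dx_um, self.dy_um))


def measure_displacement(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    pixel_um: float,
    min_confidence: float = 0.03,
) -> DisplacementMeasurement:
    """Sub-pixel displacement of ``frame_b`` relative to ``frame_a`` in um.

    Automates the manual video-frame distance measurements used to calibrate
    stage motion: the registration shift in pixels times the pixel size.
    Low-confidence registrations (featureless or decorrelated content) are
    flagged rather than silently trusted.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be > 0")
    est = phase_correlate(np.asarray(frame_a, float), np.asarray(frame_b, float))
    return DisplacementMeasurement(
        dx_um=est.dx * pixel_um,
        dy_um=est.dy * pixel_um,
        dx_px=est.dx,
        dy_px=est.dy,
        confidence=est.confidence,
        flagged=est.confidence < min_confidence,
    )


def drift_track(
    frame_series: list[np.ndarray] | np.ndarray,
    pixel_um: float,
    timestamps=None,
) -> tuple[pd.DataFrame, dict]:
    """Track apparent stage drift across a time series of frames.

    Every frame is registered against frame 0.  Returns the per-frame
    displacement table and a summary with the maximum absolute drift per
    axis (px and um).
    """
    frames = [np.asarray(f, float) for f in frame_series]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track drift")
    if timestamps is None:
        timestamps = list(range(len(frames)))
    if len(timestamps) != len(frames):
        raise ValueError("timestamps length must match frame count")
    rows = []
    for i, frame in enumerate(frames):
        if i == 0:
            rows.append(
                dict(frame=0, time=timestamps[0], dx_px=0.0, dy_px=0.0,
                     dx_um=0.0, dy_um=0.0, confidence=1.0, flagged=False)
            )
            continue
        m = measure_displacement(frames[0], frame, pixel_um)
        rows.append(
            dict(frame=i, time=timestamps[i], dx_px=m.dx_px, dy_px=m.dy_px,
                 dx_um=m.dx_um, dy_um=m.dy_um, confidence=m.confidence,
                 flagged=m.flagged)
        )
    table = pd.DataFrame(rows)
    summary = {
        "max_abs_dx_px": float(table["dx_px"].abs().max()),
        "max_abs_dy_px": float(table["dy_px"].abs().max()),
        "max_abs_dx_um": float(table["dx_um"].abs().max()),
        "max_abs_dy_um": float(table["dy_um"].abs().max()),
        "n_flagged": int(table["flagged"].sum()),
    }
    return table, summary


# ---------------------------------------------------------------------------
# actuator step calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationRecord:
    """Mean measured travel for one (axis, direction, step-size) condition.

    ``sd_um`` is only present when n >= 2 *and* the per-repeat distances
    were individually resolvable (small step sizes measured as an aggregate
    distance carry no spread information).
    """

    axis: str
    direction: str
    step_size: float
    n: int
    mean_um: float
    sd_um: float | None
    load_g: float | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class SlopeFit:
    """Least-squares um-per-unit slope through the origin, with its SE."""

    um_per_unit: float
    stderr: float
    n_points: int


@dataclass
class CalibrationResult:
    records: list[CalibrationRecord]
    slopes: dict[tuple[str, str], SlopeFit]

    def to_calibration(self) -> Calibration:
        """Command-unit conversion table usable by ``StageState.move_to``."""
        return Calibration(
            {key: fit.um_per_unit for key, fit in self.slopes.items()}
        )


def calibrate_steps(
    measurements: pd.DataFrame,
    load_g: float | None = None,
    metadata: dict | None = None,
) -> CalibrationResult:
    """Summarize repeated step-distance measurements into calibration records.

    ``measurements`` needs columns ``axis``, ``direction`` (up/down),
    ``step_size`` (command units) and ``distance_um`` (one row per repeat);
    an optional boolean ``resolvable`` column marks conditions whose repeats
    were individually measurable (default True).  Per (axis, direction,
    step_size) the mean and — when defined — SD are recorded; per
    (axis, direction) a um-per-unit slope is fit by least squares through
    the origin across step sizes (zero command = zero displacement is
    physical).  Empty groups are skipped with a warning.
    """
    required = {"axis", "direction", "step_size", "distance_um"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    df = measurements.copy()
    if "resolvable" not in df.columns:
        df["resolvable"] = True

    records: list[CalibrationRecord] = []
    slopes: dict[tuple[str, str], SlopeFit] = {}
    for (axis, direction), per_dir in df.groupby(["axis", "direction"], sort=True):
        for step_size, grp in per_dir.groupby("step_size", sort=True):
            dist = grp["distance_um"].to_numpy(float)
            dist = dist[np.isfinite(dist)]
            if dist.size == 0:
                warnings.warn(
                    f"empty measurement group ({axis}, {direction}, {step_size}); skipped",
                    stacklevel=2,
                )
                continue
            resolvable = bool(grp["resolvable"].all())
            sd = float(np.std(dist, ddof=1)) if (dist.size >= 2 and resolvable) else None
            records.append(
                CalibrationRecord(
                    axis=str(axis),
                    direction=str(direction),
                    step_size=float(step_size),
                    n=int(dist.size),
                    mean_um=float(np.mean(dist)),
                    sd_um=sd,
                    load_g=load_g,
                    metadata=dict(metadata or {}),
                )
            )
        s = per_dir["step_size"].to_numpy(float)
        d = np.abs(per_dir["distance_um"].to_numpy(float))
        ok = np.isfinite(s) & np.isfinite(d) & (s > 0)
        s, d = s[ok], d[ok]
        if s.size == 0:
            continue
        # weighted least squares through the origin with 1/s^2 weights: the
        # actuator error is multiplicative (a fixed fraction of the step),
        # so per-unit ratios d/s are iid and their mean is the BLUE slope
        ratios = d / s
        slope = float(ratios.mean())
        if s.size > 1:
            stderr = float(ratios.std(ddof=1) / np.sqrt(s.size))
        else:
            stderr = float("nan")
        slopes[(str(axis), str(direction))] = SlopeFit(slope, stderr, int(s.size))
    return CalibrationResult(records, slopes)


# ---------------------------------------------------------------------------
# illumination uniformity
# ---------------------------------------------------------------------------

def illumination_uniformity(flat_field_image: np.ndarray) -> dict:
    """Report corner/centre illumination ratio and coefficient of variation.

    The image is smoothed with a broad Gaussian (1/16 of the image size) to
    suppress shot noise and structure, then the mean of the four corner
    patches is compared with a central patch.  Both metrics are invariant to
    global intensity scaling.
    """
    img = np.asarray(flat_field_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("flat-field image must be single-channel 2D")
    h, w = img.shape
    # mild smoothing only: a broad kernel would drag the corner estimate
    # toward the interior and understate the falloff
    sigma = max(min(h, w) / 64.0, 1.0)
    smooth = ndimage.gaussian_filter(img, sigma=sigma, mode="nearest")
    centre = smooth[h // 2 - 1 : h // 2 + 2, w // 2 - 1 : w // 2 + 2].mean()
    corners = np.mean(
        [smooth[0, 0], smooth[0, -1], smooth[-1, 0], smooth[-1, -1]]
    )
    mean = smooth.mean()
    cv = float(smooth.std() / mean) if mean != 0 else 0.0
    return {
        "corner_centre_ratio": float(corners / centre) if centre != 0 else float("nan"),
        "cv": cv,
        "centre_mean": float(centre),
        "corner_mean": float(corners),
    }
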