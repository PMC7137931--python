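"""Sub-pixel translation registration by windowed phase correlation.

One registration engine, two consumers: tile stitching and the QC
displacement / drift measurements.  Two estimators share its conventions:
:func:`phase_correlate`, classical phase correlation — Hann-windowed,
mean-subtracted inputs, normalized cross-power spectrum, inverse FFT — with
the peak searched only inside a configurable radius (stitching knows the
nominal plan offset, so a global search is unnecessary and spurious distant
peaks are excluded) and refined to sub-pixel precision by a separable
quadratic fit around the integer peak; and :func:`masked_ncc_shift`,
a sliding normalized cross-correlation for integer displacements that can
rival the overlap size.

Sign convention: the returned shift ``(dy, dx)`` satisfies
``b(r, c) ~= a(r - dy, c - dx)`` — it is the displacement of image ``b``'s
content relative to ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ShiftEstimate", "phase_correlate", "masked_ncc_shift"]


@dataclass(frozen=True)
class ShiftEstimate:
    """A sub-pixel shift (rows, cols) with a [0, 1] confidence score."""

    dy: float
    dx: float
    confidence: float

    @property
    def vector(self) -> tuple[float, float]:
        return (self.dy, self.dx)


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0]) if shape[0] > 1 else np.ones(1)
    wx = np.hanning(shape[1]) if shape[1] > 1 else np.ones(1)
    return np.outer(wy, wx)


def _quadratic_offset(cm: float, c0: float, cp: float) -> float:
    """Vertex offset of a parabola through three equispaced samples."""
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:  # not a maximum; keep the integer location
        return 0.0
    off = 0.5 * (cm - cp) / denom
    if abs(off) < 1e-9:  # numerically symmetric peak: exactly centred
        return 0.0
    return float(np.clip(off, -0.5, 0.5))


def phase_correlate(
    a: np.ndarray,
    b: np.ndarray,
    search_radius: float | None = None,
    center: tuple[float, float] = (0.0, 0.0),
    window: bool = True,
    pad: bool = False,
) -> ShiftEstimate:
    """Estimate the translation of ``b`` relative to ``a``.

    Parameters
    ----------
    a, b:
        Equal-shape 2D images.
    search_radius, center:
        If ``search_radius`` is given, the correlation peak is searched only
        within that radius (px) of the expected shift ``center``; correlation
        mass outside is ignored.
    window:
        Apply a 2D Hann window before the FFT (suppresses wrap-around edges
        on non-periodic content).
    pad:
        Zero-pad to twice the image size before transforming, making the
        correlation linear instead of circular: shifts up to a full image
        size are then unambiguous (no aliasing), at the cost of a diluted
        peak.

    Returns
    -------
    ShiftEstimate
        Sub-pixel shift plus confidence = the normalized correlation-peak
        height, ~1 for a clean single peak and near 0 for featureless or
        unrelated inputs.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(f"images must be equal-shape 2D, got {a.shape} vs {b.shape}")
    h, w = a.shape
    a = a - a.mean()
    b = b - b.mean()
    if not a.any() or not b.any():
        return ShiftEstimate(0.0, 0.0, 0.0)
    if window:
        win = _hann2d(a.shape)
        a = a * win
        b = b * win
    if pad:
        h, w = 2 * h, 2 * w
        ap = np.zeros((h, w))
        bp = np.zeros((h, w))
        ap[: a.shape[0], : a.shape[1]] = a
        bp[: b.shape[0], : b.shape[1]] = b
        a, b = ap, bp

    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    cross = cross / np.maximum(mag, 1e-12 * mag.max() if mag.max() > 0 else 1e-30)
    corr = np.real(np.fft.ifft2(cross))
    corr = np.fft.fftshift(corr)
    cy, cx = h // 2, w // 2  # corr[cy, cx] corresponds to zero shift

    if search_radius is not None:
        yy, xx = np.mgrid[0:h, 0:w]
        shift_y = yy - cy
        shift_x = xx - cx
        dist2 = (shift_y - center[0]) ** 2 + (shift_x - center[1]) ** 2
        masked = np.where(dist2 <= search_radius**2, corr, -np.inf)
        if not np.isfinite(masked).any():
            return ShiftEstimate(float(center[0]), float(center[1]), 0.0)
        peak = np.unravel_index(int(np.argmax(masked)), corr.shape)
    else:
        peak = np.unravel_index(int(np.argmax(corr)), corr.shape)

    py, px = int(peak[0]), int(peak[1])
    c0 = corr[py, px]
    # separable quadratic refinement (neighbors wrap via the periodic corr)
    dy_off = _quadratic_offset(corr[(py - 1) % h, px], c0, corr[(py + 1) % h, px])
    dx_off = _quadratic_offset(corr[py, (px - 1) % w], c0, corr[py, (px + 1) % w])
    dy = (py - cy) + dy_off
    dx = (px - cx) + dx_off
    confidence = float(np.clip(c0, 0.0, 1.0))
    return ShiftEstimate(float(dy), float(dx), confidence)


def masked_ncc_shift(
    a: np.ndarray,
    b: np.ndarray,
    search_radius: float,
    center: tuple[float, float] = (0.0, 0.0),
    min_overlap_px: int = 16,
    min_overlap_area: float | None = None,
) -> ShiftEstimate:
    """Integer displacement of ``b`` relative to ``a`` by sliding Pearson NCC.

    Computes, via FFT cross-correlations of the images and their support
    masks, the normalized cross-correlation of the *actual overlap* at every
    integer displacement, and returns the best one within ``search_radius``
    of ``center``.  Unlike circular phase correlation this handles
    displacements comparable to (or larger than) the overlap itself, which
    is the regime of open-loop stages whose step error rivals the planned
    tile overlap.  Offsets whose overlap area falls below
    ``min_overlap_area`` (default ``min_overlap_px`` squared) are excluded —
    tiny overlaps of smooth content produce spuriously high correlations.

    Confidence is the Pearson correlation coefficient of the overlap at the
    chosen displacement (~1 for matching content, ~0 for unrelated frames).
    Sign convention matches :func:`phase_correlate`.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(f"images must be equal-shape 2D, got {a.shape} vs {b.shape}")
    h, w = a.shape
    H, W = 2 * h, 2 * w

    def _pad(img):
        out = np.zeros((H, W))
        out[:h, :w] = img
        return out

    fa = np.fft.rfft2(_pad(a))
    fb = np.fft.rfft2(_pad(b))
    fa2 = np.fft.rfft2(_pad(a * a))
    fb2 = np.fft.rfft2(_pad(b * b))
    fm = np.fft.rfft2(_pad(np.ones((h, w))))

    def _xcorr(f1, f2):
        # correlation of item1 with item2: sum_p item1(p) item2(p - t)
        return np.fft.fftshift(np.fft.irfft2(f2 * np.conj(f1), s=(H, W)))

    n = _xcorr(fm, fm)          # overlap pixel count at each displacement
    s_a = _xcorr(fa, fm)        # sum of a over the overlap
    s_b = _xcorr(fm, fb)        # sum of b over the overlap
    s_ab = _xcorr(fa, fb)
    s_aa = _xcorr(fa2, fm)
    s_bb = _xcorr(fm, fb2)

    n = np.maximum(n, 1e-9)
    cov = s_ab - s_a * s_b / n
    var_a = np.maximum(s_aa - s_a**2 / n, 0.0)
    var_b = np.maximum(s_bb - s_b**2 / n, 0.0)
    denom = np.sqrt(var_a * var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 1e-9, cov / np.maximum(denom, 1e-12), 0.0)

    cy, cx = H // 2, W // 2
    yy, xx = np.mgrid[0:H, 0:W]
    dist2 = (yy - cy - center[0]) ** 2 + (xx - cx - center[1]) ** 2
    area = min_overlap_area if min_overlap_area is not None else min_overlap_px**2
    valid = (dist2 <= search_radius**2) & (n >= area)
    if not valid.any():
        return ShiftEstimate(float(center[0]), float(center[1]), 0.0)
    masked = np.where(valid, ncc, -np.inf)
    py, px = np.unravel_index(int(np.argmax(masked)), masked.shape)
    return ShiftEstimate(
        float(py - cy), float(px - cx), float(np.clip(ncc[py, px], 0.0, 1.0))
    )
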