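"""Synthetic specimens and the virtual camera.

This module replaces the physical sample, objective and camera for every test
in the package.  It provides

* :class:`SpecimenVolume` — a 3D fluorescence intensity field with physical
  voxel pitch, the ground truth for all imaging;
* :func:`make_nervenet_specimen` — a whole-mount-like specimen: a smoothly
  curved height surface carrying a mesh of bright filaments, so the focal
  plane varies across XY the way it does in a real flat-mounted epithelium
  with an underlying nerve net;
* :func:`make_usaf_target` / :func:`make_slanted_edge` — resolution-chart
  images (three-bar USAF-1951 elements, slanted edges) for optical QC;
* :func:`render_frame` — the virtual camera: per-plane defocus blur, radial
  vignetting, photon + read noise, integer quantization.

Coordinate conventions (used everywhere in the package):

* physical units are micrometres (um);
* image row 0 corresponds to minimum Y, column 0 to minimum X;
* the stage position is the physical location of the FOV centre, and stage +Z
  moves the focal plane deeper into the specimen (larger specimen z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, special

from .qc import res_lp, res_cc

__all__ = [
    "SpecimenVolume",
    "OpticsModel",
    "make_nervenet_specimen",
    "make_usaf_target",
    "make_slanted_edge",
    "render_frame",
    "write_stack",
    "read_stack",
]


@dataclass
class SpecimenVolume:
    """A 3D intensity field with physical calibration.

    ``intensity`` is indexed ``[z, y, x]`` in arbitrary fluorescence units
    (>= 0).  ``origin`` is the physical (x, y, z) position in um of voxel
    (0, 0, 0); ``pitch_xy`` and ``pitch_z`` are um per voxel.
    """

    intensity: np.ndarray
    pitch_xy: float
    pitch_z: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.ndim != 3 or 0 in self.intensity.shape:
            raise ValueError("intensity must be a non-empty 3D array [z, y, x]")
        if self.pitch_xy <= 0 or self.pitch_z <= 0:
            raise ValueError("voxel pitches must be > 0")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """(x, y, z) physical extent in um."""
        nz, ny, nx = self.intensity.shape
        return (nx * self.pitch_xy, ny * self.pitch_xy, nz * self.pitch_z)

    def z_planes_um(self) -> np.ndarray:
        nz = self.intensity.shape[0]
        return self.origin[2] + np.arange(nz) * self.pitch_z


@dataclass(frozen=True)
class OpticsModel:
    """The imaging model of the virtual camera.

    ``na``/``wavelength_nm`` describe the objective (defaults: the 20x water
    immersion lens, NA 0.5, FITC-band 530 nm emission); ``pixel_um`` is the
    camera-plane pixel size in specimen units (0.386 um/pixel at 20x).
    Defocus is modelled as a Gaussian kernel whose sigma (um) grows linearly
    with defocus distance at ``defocus_blur_um_per_um``; vignetting as a
    radial quadratic falloff reaching ``vignette_strength`` at the corners
    (the paraxial limit of a cosine-fourth law).  Noise combines Poisson
    photon noise (``photon_scale`` photons per intensity unit) with Gaussian
    read noise; defaults give SNR ~ 20 on bright structures.
    """

    na: float = 0.5
    wavelength_nm: float = 530.0
    pixel_um: float = 0.386
    fov_px: int = 256
    defocus_blur_um_per_um: float = 0.4
    vignette_strength: float = 0.05
    photon_scale: float = 0.4
    read_noise: float = 2.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not 0.0 < self.na <= 1.0:
            raise ValueError("na must be in (0, 1]")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be > 0")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must be in [0, 1]")
        if self.fov_px < 2:
            raise ValueError("fov_px must be >= 2")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def fov_um(self) -> float:
        return self.fov_px * self.pixel_um

    @property
    def full_scale(self) -> int:
        return 2 ** self.bit_depth - 1


# ---------------------------------------------------------------------------
# specimen generators
# ---------------------------------------------------------------------------

def _height_surface(
    nx: int,
    ny: int,
    pitch_xy: float,
    mid_z: float,
    amplitude_um: float,
    tilt: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth random height field h(y, x) in um: low-order cosines + tilt."""
    x = np.arange(nx) * pitch_xy
    y = np.arange(ny) * pitch_xy
    xx, yy = np.meshgrid(x, y)
    h = np.full((ny, nx), mid_z)
    h += tilt[0] * xx + tilt[1] * yy
    if amplitude_um > 0:
        span = max(x[-1] if nx > 1 else 1.0, y[-1] if ny > 1 else 1.0)
        for _ in range(4):
            kx, ky = rng.uniform(0.5, 2.0, size=2) * 2 * np.pi / span
            phase = rng.uniform(0, 2 * np.pi, size=2)
            h += (amplitude_um / 4.0) * np.cos(kx * xx + phase[0]) * np.cos(
                ky * yy + phase[1]
            )
    return h


def make_nervenet_specimen(
    extent_um: tuple[float, float, float] = (500.0, 500.0, 50.0),
    n_filaments: int = 40,
    seed: int = 0,
    *,
    pitch_xy: float = 1.0,
    pitch_z: float = 2.0,
    background: float = 50.0,
    filament_intensity: float = 1000.0,
    surface_amplitude_um: float | None = None,
    tilt: tuple[float, float] = (0.0, 0.0),
    filament_radius_um: float = 1.5,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SpecimenVolume:
    """Generate a nerve-net-like fluorescent volume.

    Bright filaments (random smooth walks, Gaussian cross-section) are laid
    on a smoothly varying height surface inside a dim background volume, so
    that the in-focus plane drifts across XY — the situation that makes
    Z-stacking and inter-tile Z-correction necessary on real tissue.

    Parameters
    ----------
    extent_um:
        Physical (x, y, z) size of the volume; all entries must be > 0.
    n_filaments:
        Number of filament walks (>= 1).  Setting ``filament_intensity=0``
        yields a background-only volume.
    surface_amplitude_um:
        Peak-to-mid amplitude of the curved height surface; defaults to a
        quarter of the Z extent.  ``tilt`` adds a planar gradient (um per um)
        for controlled focus-drift experiments.
    seed:
        Volumes are voxel-identical for identical seeds and parameters.
    """
    if any(e <= 0 for e in extent_um):
        raise ValueError(f"extent_um must be positive in all axes, got {extent_um}")
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    rng = np.random.default_rng(seed)
    nx = max(int(round(extent_um[0] / pitch_xy)), 1)
    ny = max(int(round(extent_um[1] / pitch_xy)), 1)
    nz = max(int(round(extent_um[2] / pitch_z)), 1)
    if surface_amplitude_um is None:
        surface_amplitude_um = extent_um[2] / 4.0

    mid_z = origin[2] + (nz - 1) * pitch_z / 2.0
    height = _height_surface(nx, ny, pitch_xy, mid_z, surface_amplitude_um, tilt, rng)

    # 2D filament mask: a polygonal mesh (Voronoi ridges of n_filaments
    # random cell centres), the geometry of an epithelial nerve net; mesh
    # strands are then widened to the filament radius.  Mirrored copies of
    # the points close the diagram at the domain borders.
    mask = np.zeros((ny, nx), dtype=np.float32)
    ex, ey = nx * pitch_xy, ny * pitch_xy
    pts = rng.uniform((0.0, 0.0), (ex, ey), size=(n_filaments, 2))
    all_pts = np.vstack(
        [
            pts,
            np.column_stack([-pts[:, 0], pts[:, 1]]),
            np.column_stack([2 * ex - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], -pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * ey - pts[:, 1]]),
        ]
    )
    from scipy.spatial import Voronoi

    if len(all_pts) >= 4:
        vor = Voronoi(all_pts)
        for (p1, p2), ridge in zip(vor.ridge_points, vor.ridge_vertices):
            if p1 >= n_filaments and p2 >= n_filaments:
                continue  # ridge between mirror cells only
            if -1 in ridge:
                continue
            v0, v1 = vor.vertices[ridge[0]], vor.vertices[ridge[1]]
            length = float(np.hypot(*(v1 - v0)))
            if length == 0:
                continue
            n_samp = max(int(length / (0.5 * pitch_xy)), 2)
            for t in np.linspace(0.0, 1.0, n_samp):
                x_um, y_um = v0 + t * (v1 - v0)
                ixm = int(x_um / pitch_xy)
                iym = int(y_um / pitch_xy)
                if 0 <= ixm < nx and 0 <= iym < ny:
                    mask[iym, ixm] = 1.0
    sigma_px = filament_radius_um / pitch_xy / 2.0
    if sigma_px > 0:
        mask = ndimage.gaussian_filter(mask, sigma_px)
        if mask.max() > 0:
            mask /= mask.max()

    vol = np.full((nz, ny, nx), background, dtype=np.float32)
    if filament_intensity > 0 and mask.max() > 0:
        sigma_z = max(filament_radius_um, pitch_z / 2.0)
        z_planes = origin[2] + np.arange(nz) * pitch_z
        for k, zk in enumerate(z_planes):
            w = np.exp(-((zk - height) ** 2) / (2.0 * sigma_z**2))
            vol[k] += filament_intensity * mask * w.astype(np.float32)
    return SpecimenVolume(vol, pitch_xy, pitch_z, origin)


def make_usaf_target(
    max_group: int,
    pixel_um: float,
    *,
    min_group: int | None = None,
    margin_px: int = 16,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render USAF-1951 three-bar elements and their geometry table.

    Elements 1–6 of each group from ``min_group`` (default ``max_group``) to
    ``max_group`` are drawn as vertical three-bar patterns on a dark field
    (bright = 1.0, dark = 0.0), stacked left to right.  The line-pair period
    of group G element E is ``1000 / RES_LP(G, E)`` um with
    ``RES_LP = 2^(G + (E-1)/6)`` lp/mm.  The geometry table records, per
    element, the bar-region bounding box in pixels plus its period and
    resolution.

    Raises ``ValueError`` naming the finest resolvable element when the
    requested finest element would have bar lines narrower than 2 pixels.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be > 0")
    if min_group is None:
        min_group = max_group
    if min_group > max_group:
        raise ValueError("min_group must be <= max_group")

    def line_width_px(g: int, e: int) -> float:
        return res_cc(res_lp(g, e)) / 2.0 / pixel_um

    if line_width_px(max_group, 6) < 2.0:
        finest = None
        for g in range(max_group, min_group - 2, -1):
            for e in range(6, 0, -1):
                if line_width_px(g, e) >= 2.0:
                    finest = (g, e)
                    break
            if finest:
                break
        hint = (
            f"finest resolvable element at {pixel_um} um/pixel is "
            f"group {finest[0]} element {finest[1]}"
            if finest
            else "no element resolvable at this pixel size"
        )
        raise ValueError(
            f"group {max_group} element 6 is undersampled (< 2 px per line); {hint}"
        )

    blocks = []
    rows = []
    for g in range(min_group, max_group + 1):
        for e in range(1, 7):
            lp = res_lp(g, e)
            period_um = res_cc(lp)
            half_px = max(int(round(period_um / 2.0 / pixel_um)), 2)
            # three vertical bars: bar/gap widths = half-period
            w = 5 * half_px
            h = 5 * half_px
            block = np.zeros((h, w), dtype=np.float32)
            for b in range(3):
                block[:, 2 * b * half_px : (2 * b + 1) * half_px] = 1.0
            blocks.append((g, e, block, period_um, lp))

    width = sum(b[2].shape[1] for b in blocks) + margin_px * (len(blocks) + 1)
    height = max(b[2].shape[0] for b in blocks) + 2 * margin_px
    image = np.zeros((height, width), dtype=np.float32)
    x0 = margin_px
    for g, e, block, period_um, lp in blocks:
        h, w = block.shape
        y0 = margin_px
        image[y0 : y0 + h, x0 : x0 + w] = block
        rows.append(
            {
                "group": g,
                "element": e,
                "x0": x0,
                "y0": y0,
                "x1": x0 + w,
                "y1": y0 + h,
                "period_um": period_um,
                "res_lp_per_mm": lp,
            }
        )
        x0 += w + margin_px
    return image, pd.DataFrame(rows)


def make_slanted_edge(
    size_px: int = 128,
    angle_deg: float = 5.0,
    *,
    blur_sigma_px: float = 0.0,
    oversample: int = 8,
    low: float = 0.1,
    high: float = 0.9,
) -> np.ndarray:
    """Synthesize a slanted step edge with exact area sampling.

    The edge is a straight boundary tilted ``angle_deg`` off vertical through
    the image centre; each pixel integrates the (optionally Gaussian-blurred)
    step over an ``oversample`` x ``oversample`` subgrid, which reproduces
    the pixel-aperture response analytically to high accuracy.  Used as the
    ground-truth input for slant-edge MTF estimation.
    """
    n = size_px
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    ys, xs = np.meshgrid(sub, sub, indexing="ij")
    rows = np.arange(n)[:, None, None, None] + ys[None, None]
    cols = np.arange(n)[None, :, None, None] + xs[None, None]
    slope = np.tan(np.deg2rad(angle_deg))
    centre = (n - 1) / 2.0
    # signed distance (in px, along x) from the edge x = centre + slope*(y-centre)
    d = cols - (centre + slope * (rows - centre))
    d = d * np.cos(np.deg2rad(angle_deg))  # edge-normal distance
    if blur_sigma_px > 0:
        profile = 0.5 * (1.0 + special.erf(d / (blur_sigma_px * np.sqrt(2.0))))
    else:
        profile = (d >= 0).astype(float)
    img = low + (high - low) * profile.mean(axis=(2, 3))
    return img.astype(np.float32)


# ---------------------------------------------------------------------------
# the virtual camera
# ---------------------------------------------------------------------------

def _vignette(fov_px: int, strength: float) -> np.ndarray:
    c = (fov_px - 1) / 2.0
    yy, xx = np.mgrid[0:fov_px, 0:fov_px]
    r2 = ((xx - c) ** 2 + (yy - c) ** 2) / (2 * c**2)  # 1.0 at the corners
    return 1.0 - strength * r2


class _PlaneCache:
    """Resampled + Fourier-transformed volume planes for one XY position.

    A Z-stack acquires many frames at the same XY with only the focal depth
    changing; the per-plane resampling and forward FFTs are identical across
    the stack, so they are computed once and reused.  The resampled region
    is padded by half a FOV on every side with real neighbouring specimen
    content, which keeps the periodic wrap-around of the Fourier-domain blur
    away from the cropped frame.
    """

    def __init__(self, vol: SpecimenVolume, cx: float, cy: float, optics: OpticsModel):
        self.key = (id(vol), float(cx), float(cy), optics.fov_px, optics.pixel_um)
        n = optics.fov_px
        self.pad = n // 2
        m = n + 2 * self.pad
        x0, y0, _ = vol.origin
        cols_um = cx + (np.arange(m) - (m - 1) / 2.0) * optics.pixel_um
        rows_um = cy + (np.arange(m) - (m - 1) / 2.0) * optics.pixel_um
        ix = (cols_um - x0) / vol.pitch_xy
        iy = (rows_um - y0) / vol.pitch_xy
        coords_row = np.broadcast_to(iy[:, None], (m, m))
        coords_col = np.broadcast_to(ix[None, :], (m, m))
        self.z_planes_um = vol.z_planes_um()
        self.plane_ffts = [
            np.fft.rfft2(
                ndimage.map_coordinates(
                    vol.intensity[k], [coords_row, coords_col], order=1, mode="nearest"
                )
            )
            for k in range(vol.intensity.shape[0])
        ]
        fy = np.fft.fftfreq(m)[:, None]
        fx = np.fft.rfftfreq(m)[None, :]
        self.freq2 = fy**2 + fx**2
        self.m = m


def render_frame(
    vol: SpecimenVolume,
    pos: dict[str, float],
    optics: OpticsModel,
    seed: int | np.random.Generator | None = 0,
    *,
    cache: _PlaneCache | None = None,
) -> np.ndarray:
    """Render one camera frame of ``vol`` at stage position ``pos``.

    Every volume plane is resampled onto the camera grid and blurred with a
    Gaussian of sigma ``|z_plane - pos['z']| * defocus_blur_um_per_um`` (um,
    converted to pixels; applied in the Fourier domain, which conserves the
    plane mean exactly); the blurred planes are summed, vignetted, noised
    (Poisson photon + Gaussian read noise) and quantized to the camera bit
    depth.  Deterministic for a fixed seed.

    Raises ``ValueError`` if the FOV lies fully outside the volume in XY —
    a black frame would silently hide scan-planning bugs.
    """
    n = optics.fov_px
    half = optics.fov_um / 2.0
    cx, cy, z_focus = float(pos["x"]), float(pos["y"]), float(pos["z"])
    ex, ey, _ = vol.extent_um
    x0, y0, _ = vol.origin
    if cx + half <= x0 or cx - half >= x0 + ex or cy + half <= y0 or cy - half >= y0 + ey:
        raise ValueError(
            f"FOV centred at ({cx:.1f}, {cy:.1f}) um lies fully outside the "
            f"specimen extent x=[{x0:.1f}, {x0 + ex:.1f}], y=[{y0:.1f}, {y0 + ey:.1f}] um"
        )

    if cache is None or cache.key != (id(vol), cx, cy, n, optics.pixel_um):
        cache = _PlaneCache(vol, cx, cy, optics)
    accum = np.zeros_like(cache.plane_ffts[0])
    scale = optics.defocus_blur_um_per_um / optics.pixel_um
    for z_um, plane_fft in zip(cache.z_planes_um, cache.plane_ffts):
        sigma_px = abs(z_um - z_focus) * scale
        if sigma_px > 1e-3:
            accum += plane_fft * np.exp(-2.0 * np.pi**2 * sigma_px**2 * cache.freq2)
        else:
            accum += plane_fft
    padded = np.fft.irfft2(accum, s=(cache.m, cache.m))
    frame = padded[cache.pad : cache.pad + n, cache.pad : cache.pad + n].copy()

    if optics.vignette_strength > 0:
        frame *= _vignette(n, optics.vignette_strength)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if optics.photon_scale > 0:
        frame = rng.poisson(np.maximum(frame, 0.0) * optics.photon_scale) / optics.photon_scale
    if optics.read_noise > 0:
        frame = frame + rng.normal(0.0, optics.read_noise, size=frame.shape)

    frame = np.clip(np.rint(frame), 0, optics.full_scale)
    dtype = np.uint8 if optics.bit_depth == 8 else np.uint16
    return frame.astype(dtype)


# ---------------------------------------------------------------------------
# TIFF I/O with JSON sidecar metadata
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: np.ndarray, metadata: dict | None = None) -> None:
    """Write a 2D image or 3D stack as (multi-page) TIFF with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack))
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(metadata, indent=2, sort_keys=True)
        )


def read_stack(path: str | Path) -> tuple[np.ndarray, dict | None]:
    """Read a TIFF written by :func:`write_stack`; returns (array, metadata)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return data, meta
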