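"""Mosaic assembly of overlapping MIP tiles.

Open-loop piezo stages place tiles with up to ±20 % step error, so composites
cannot be assembled from commanded coordinates alone; the 25–30 % tile
overlap exists precisely so that image-content registration can recover the
true tile placement.  The pipeline here is:

1. :func:`pairwise_offset` — locate each adjacent pair's integer offset by
   sliding normalized cross-correlation searched near the nominal plan
   offset (robust when the placement error rivals the overlap width), then
   refine to sub-pixel by phase correlation of the aligned overlap;
   featureless overlaps fall back to the nominal offset with a
   low-confidence flag.
2. :func:`global_positions` — solve the weighted least-squares system that
   best agrees with all pairwise offsets (anchor tile at the origin;
   low-confidence edges down-weighted), which distributes any inconsistent
   edge across the redundant grid graph.
3. :func:`compose` — paste tiles onto the bounding-box canvas with linear
   feather blending across the overlaps.

Tile positions are (row, col) pixel coordinates of each tile's top-left
corner; for rendered tiles these are proportional to the stage position
(``um / pixel_um``).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .registration import masked_ncc_shift, phase_correlate

__all__ = [
    "OffsetEstimate",
    "pairwise_offset",
    "global_positions",
    "compose",
    "grid_edges",
    "stitch_scan",
]

MIN_OVERLAP_PX = 32


@dataclass
class OffsetEstimate:
    """Estimated pixel offset (position of tile B minus tile A)."""

    id_a: object
    id_b: object
    dy: float
    dx: float
    confidence: float
    fallback: bool = False  # True when the nominal offset was kept

    @property
    def vector(self) -> tuple[float, float]:
        return (self.dy, self.dx)


def _overlap_slices(shape_a, shape_b, dy: int, dx: int):
    """Equal-shape crops of the nominal overlap of two tiles."""
    ha, wa = shape_a
    hb, wb = shape_b
    ry0, ry1 = max(0, dy), min(ha, dy + hb)
    rx0, rx1 = max(0, dx), min(wa, dx + wb)
    if ry1 - ry0 <= 0 or rx1 - rx0 <= 0:
        return None
    a_sl = (slice(ry0, ry1), slice(rx0, rx1))
    b_sl = (slice(ry0 - dy, ry1 - dy), slice(rx0 - dx, rx1 - dx))
    return a_sl, b_sl


def pairwise_offset(
    im_a: np.ndarray,
    im_b: np.ndarray,
    nominal_offset_px: tuple[float, float],
    search_radius_px: float = 10.0,
    *,
    min_confidence: float = 0.10,
    id_a: object = None,
    id_b: object = None,
) -> OffsetEstimate:
    """Refine the offset of tile B relative to tile A around the plan value.

    The nominal overlap (which must be at least 32 px wide in both
    directions) anchors a sliding-NCC search within ``search_radius_px`` of
    the plan offset; the winning integer offset is then refined to
    sub-pixel by phase correlation of the aligned overlap.  If the aligned
    overlap's correlation falls below ``min_confidence`` (featureless or
    decorrelated content) the nominal offset is returned flagged as a
    fallback.
    """
    a = np.asarray(im_a, dtype=np.float64)
    b = np.asarray(im_b, dtype=np.float64)
    dy_n, dx_n = float(nominal_offset_px[0]), float(nominal_offset_px[1])
    d_int = (int(round(dy_n)), int(round(dx_n)))
    sl = _overlap_slices(a.shape, b.shape, *d_int)
    if sl is None:
        raise ValueError(
            f"tiles do not overlap at nominal offset ({dy_n:.1f}, {dx_n:.1f})"
        )
    if min(a[sl[0]].shape) < MIN_OVERLAP_PX:
        raise ValueError(
            f"overlap region {a[sl[0]].shape} narrower than {MIN_OVERLAP_PX} px; "
            "increase the planned overlap or tile size"
        )
    # Whole-tile sliding NCC locates the integer peak: it evaluates the
    # actual overlap at every candidate displacement, so offsets displaced
    # from nominal by amounts rivalling the overlap width itself (open-loop
    # piezo error) are still found.  Tile B showing scene content at +t
    # relative to A appears displaced by -t, so the search centres on
    # -nominal.
    nominal_area = (a.shape[0] - abs(d_int[0])) * (a.shape[1] - abs(d_int[1]))
    est = masked_ncc_shift(
        a,
        b,
        search_radius=search_radius_px,
        center=(-dy_n, -dx_n),
        min_overlap_area=max((MIN_OVERLAP_PX // 2) ** 2, 0.3 * nominal_area),
    )
    dy_i = -round(est.dy)
    dx_i = -round(est.dx)
    sl2 = _overlap_slices(a.shape, b.shape, dy_i, dx_i)
    if sl2 is None or min(a[sl2[0]].shape) < MIN_OVERLAP_PX // 2:
        return OffsetEstimate(id_a, id_b, dy_n, dx_n, 0.0, fallback=True)
    a2, b2 = a[sl2[0]], b[sl2[1]]
    # confidence: Pearson correlation of the integer-aligned overlap —
    # ~1 for genuinely matching content, ~0 for featureless or unrelated
    # overlaps (the padded peak height itself is diluted by the overlap
    # fraction and is not comparable across geometries)
    sa, sb = a2.std(), b2.std()
    ncc = float(np.mean((a2 - a2.mean()) * (b2 - b2.mean())) / (sa * sb)) if sa > 0 and sb > 0 else 0.0
    if ncc < min_confidence:
        return OffsetEstimate(id_a, id_b, dy_n, dx_n, max(ncc, 0.0), fallback=True)
    # Sub-pixel refinement on the aligned overlap: when the true offset is
    # an integer the crops are pixel-identical, the correlation peak is an
    # exactly symmetric delta and the residual is exactly 0.
    est2 = phase_correlate(a2, b2, search_radius=2.0)
    dy = dy_i - est2.dy
    dx = dx_i - est2.dx
    return OffsetEstimate(id_a, id_b, float(dy), float(dx), min(ncc, 1.0))


def global_positions(
    offsets: list[OffsetEstimate],
    tile_ids: list,
    anchor: object = None,
) -> dict:
    """Least-squares tile positions from pairwise offsets.

    Solves, independently per axis, for positions ``p`` minimizing
    ``sum_w (p_b - p_a - offset_ab)^2`` with the anchor tile (default: the
    first id) fixed at the origin.  Edge weights are the registration
    confidences (floored so fallback edges still weakly constrain the
    solution).  Raises if the pair graph does not connect all tiles,
    listing the disconnected components.
    """
    ids = list(tile_ids)
    if not ids:
        raise ValueError("no tiles")
    anchor = ids[0] if anchor is None else anchor
    index = {tid: k for k, tid in enumerate(ids)}
    if len(ids) == 1:
        return {ids[0]: (0.0, 0.0)}

    adjacency: dict[object, set] = {tid: set() for tid in ids}
    for off in offsets:
        adjacency[off.id_a].add(off.id_b)
        adjacency[off.id_b].add(off.id_a)
    seen = set()
    components = []
    for tid in ids:
        if tid in seen:
            continue
        comp = {tid}
        queue = deque([tid])
        while queue:
            cur = queue.popleft()
            for nxt in adjacency[cur]:
                if nxt not in comp:
                    comp.add(nxt)
                    queue.append(nxt)
        seen |= comp
        components.append(sorted(comp, key=str))
    if len(components) > 1:
        raise ValueError(f"pairwise offset graph is disconnected: {components}")

    n = len(ids)
    a_idx = index[anchor]
    inc = np.zeros((len(offsets), n))
    d = np.zeros((len(offsets), 2))
    conf = np.zeros(len(offsets))
    for k, off in enumerate(offsets):
        inc[k, index[off.id_b]] = 1.0
        inc[k, index[off.id_a]] = -1.0
        d[k] = (off.dy, off.dx)
        conf[k] = max(off.confidence, 0.01)

    big = 1e6
    anchor_row = np.zeros(n)
    anchor_row[a_idx] = big
    weights = conf.copy()
    sol = None
    # robust refit: after the first solve, edges with large residuals (a
    # corrupted registration that slipped through with high confidence) are
    # down-weighted so the redundant grid edges dominate
    for _ in range(3):
        w = weights[:, None]
        mat = np.vstack([inc * w, anchor_row])
        sol = np.column_stack(
            [
                np.linalg.lstsq(
                    mat, np.append(d[:, ax] * weights, 0.0), rcond=None
                )[0]
                for ax in (0, 1)
            ]
        )
        resid = np.hypot(*(inc @ sol - d).T)
        weights = conf / (1.0 + (resid / 3.0) ** 2)
    sol -= sol[a_idx]
    return {tid: (float(sol[index[tid], 0]), float(sol[index[tid], 1])) for tid in ids}


def compose(
    tiles: list[np.ndarray],
    positions: list[tuple[float, float]] | dict,
    blend_width_px: int = 16,
) -> np.ndarray:
    """Paste tiles at the given (row, col) positions with feather blending.

    Positions may be fractional; placement is rounded to the nearest pixel
    (sub-pixel resampling is deliberately not performed on quantized camera
    data).  ``blend_width_px > 0`` applies a linear feather ramp from each
    tile border, and overlapping tiles are weight-averaged; with
    ``blend_width_px = 0`` the mosaic is hard-edged and the last tile drawn
    wins.  The canvas is the bounding box of all tiles; uncovered canvas is
    zero.  Output dtype matches the input tiles.
    """
    if isinstance(positions, dict):
        keys = sorted(positions, key=str)
        pos_list = [positions[k] for k in keys]
    else:
        pos_list = list(positions)
    if len(tiles) != len(pos_list):
        raise ValueError("tiles and positions length mismatch")
    if len(tiles) == 0:
        raise ValueError("no tiles to compose")
    for p in pos_list:
        if not np.all(np.isfinite(p)):
            raise ValueError(f"non-finite tile position {p}")

    ipos = [(int(round(p[0])), int(round(p[1]))) for p in pos_list]
    y0 = min(p[0] for p in ipos)
    x0 = min(p[1] for p in ipos)
    y1 = max(p[0] + t.shape[0] for p, t in zip(ipos, tiles))
    x1 = max(p[1] + t.shape[1] for p, t in zip(ipos, tiles))
    h, w = y1 - y0, x1 - x0
    dtype = np.asarray(tiles[0]).dtype

    if blend_width_px <= 0:
        canvas = np.zeros((h, w), dtype=dtype)
        for (py, px), tile in zip(ipos, tiles):
            r, c = py - y0, px - x0
            canvas[r : r + tile.shape[0], c : c + tile.shape[1]] = tile
        return canvas

    num = np.zeros((h, w), dtype=np.float64)
    den = np.zeros((h, w), dtype=np.float64)
    for (py, px), tile in zip(ipos, tiles):
        tile = np.asarray(tile, dtype=np.float64)
        th, tw = tile.shape
        ry = np.minimum(np.arange(th) + 1, th - np.arange(th))
        rx = np.minimum(np.arange(tw) + 1, tw - np.arange(tw))
        wgt = np.minimum.outer(ry, rx).astype(np.float64)
        np.clip(wgt / blend_width_px, None, 1.0, out=wgt)
        r, c = py - y0, px - x0
        num[r : r + th, c : c + tw] += tile * wgt
        den[r : r + th, c : c + tw] += wgt
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(dtype)


# ---------------------------------------------------------------------------
# scan-level convenience
# ---------------------------------------------------------------------------

def grid_edges(nx: int, ny: int) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All 4-adjacent tile pairs of an nx x ny grid, keyed (i, j)."""
    edges = []
    for j in range(ny):
        for i in range(nx):
            if i + 1 < nx:
                edges.append(((i, j), (i + 1, j)))
            if j + 1 < ny:
                edges.append(((i, j), (i, j + 1)))
    return edges


def stitch_scan(
    mips: dict,
    nominal_positions_px: dict,
    nx: int,
    ny: int,
    *,
    search_radius_px: float = 15.0,
    min_confidence: float = 0.10,
    blend_width_px: int = 16,
) -> tuple[dict, list[OffsetEstimate], np.ndarray]:
    """Register and compose a full grid of MIP tiles.

    ``mips`` and ``nominal_positions_px`` map tile key (i, j) to the tile
    image and its planned top-left position in pixels.  Returns the solved
    positions (anchored so tile (0, 0) is at the nominal origin), all
    pairwise offset estimates, and the blended composite.
    """
    ids = sorted(mips)
    offsets = []
    for a, b in grid_edges(nx, ny):
        nominal = (
            nominal_positions_px[b][0] - nominal_positions_px[a][0],
            nominal_positions_px[b][1] - nominal_positions_px[a][1],
        )
        offsets.append(
            pairwise_offset(
                mips[a],
                mips[b],
                nominal,
                search_radius_px,
                min_confidence=min_confidence,
                id_a=a,
                id_b=b,
            )
        )
    positions = global_positions(offsets, ids, anchor=(0, 0))
    origin = nominal_positions_px[(0, 0)]
    positions = {
        k: (v[0] + origin[0], v[1] + origin[1]) for k, v in positions.items()
    }
    composite = compose([mips[k] for k in ids], [positions[k] for k in ids],
                        blend_width_px)
    return positions, offsets, composite
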