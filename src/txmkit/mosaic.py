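"""Mosaic stitching: motor-seeded placement, link refinement, feathered blend.

Tiles are first placed from the encoded stage motor positions; motor error is
then corrected by phase-correlating the nominal overlap strip of every
4-neighbour pair and solving all tile offsets jointly by least squares (tile 0
anchored). Blending uses a per-tile separable linear feather ramp over the
overlap so the noisier tile corners are down-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from txmkit.io import ImageFrame
from txmkit.registration import Q_MIN, Shift, phase_correlate

MIN_OVERLAP_PX = 16
FEATHER_FLOOR_PX = 8
_W_EPS = 1e-6


@dataclass
class Link:
    """A measured pairwise constraint between two overlapping tiles."""

    i: int
    j: int
    shift: Shift  # (q_j - o_j) - (q_i - o_i) in px, see refine_offsets
    used: bool = True


@dataclass
class MosaicLayout:
    tiles: list[ImageFrame]
    nominal_px: np.ndarray  # (n_tiles, 2) float (row, col)
    refined_px: np.ndarray | None = None
    overlap_frac: float = 0.2
    links: list[Link] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nominal_px = np.asarray(self.nominal_px, dtype=float)
        if self.nominal_px.shape != (len(self.tiles), 2):
            raise ValueError("one (row, col) offset per tile required")

    @property
    def offsets(self) -> np.ndarray:
        return self.refined_px if self.refined_px is not None else self.nominal_px


def nominal_positions(tiles: list[ImageFrame]) -> np.ndarray:
    """Pixel offsets from encoded motor positions.

    offset_px = (motor_um - min motor_um) * 1000 / pixel_size_nm, per axis;
    motor_y maps to rows, motor_x to columns. Fractional offsets are kept
    (rounding to integers happens only when seeding overlap crops).
    """
    mx = np.array([t.motor_x_um for t in tiles], dtype=float)
    my = np.array([t.motor_y_um for t in tiles], dtype=float)
    px = np.array([t.pixel_size_nm for t in tiles], dtype=float)
    if np.any(~np.isfinite(mx)) or np.any(~np.isfinite(my)):
        raise ValueError("missing motor positions; cannot seed mosaic layout")
    if np.any(~np.isfinite(px)) or np.any(px <= 0):
        raise ValueError("missing or invalid pixel size")
    offsets = np.stack(
        [(my - my.min()) * 1000.0 / px, (mx - mx.min()) * 1000.0 / px], axis=1
    )
    uniq = {tuple(np.round(o, 6)) for o in offsets}
    if len(uniq) < len(tiles):
        warnings.warn("tiles with identical motor positions: duplicates likely")
    return offsets


def build_layout(
    tiles: list[ImageFrame], overlap_frac: float = 0.2
) -> MosaicLayout:
    return MosaicLayout(tiles, nominal_positions(tiles), overlap_frac=overlap_frac)


def _overlap_rect(o_i, shape_i, o_j, shape_j):
    r_lo = max(o_i[0], o_j[0])
    c_lo = max(o_i[1], o_j[1])
    r_hi = min(o_i[0] + shape_i[0], o_j[0] + shape_j[0])
    c_hi = min(o_i[1] + shape_i[1], o_j[1] + shape_j[1])
    return r_lo, c_lo, r_hi, c_hi


def _neighbour_pairs(layout: MosaicLayout) -> list[tuple[int, int]]:
    """4-neighbour pairs: overlap >= MIN_OVERLAP_PX on both axes and at least
    half a tile along one axis (which excludes tiny diagonal overlaps)."""
    n = len(layout.tiles)
    nominal = np.round(layout.nominal_px).astype(int)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = layout.tiles[i].shape, layout.tiles[j].shape
            r_lo, c_lo, r_hi, c_hi = _overlap_rect(nominal[i], si, nominal[j], sj)
            h, w = r_hi - r_lo, c_hi - c_lo
            if h < MIN_OVERLAP_PX or w < MIN_OVERLAP_PX:
                continue
            if h < 0.5 * min(si[0], sj[0]) and w < 0.5 * min(si[1], sj[1]):
                continue  # diagonal neighbour
            pairs.append((i, j))
    return pairs


def refine_offsets(layout: MosaicLayout, q_min: float = Q_MIN) -> MosaicLayout:
    """Correct motor error by phase correlation over nominal overlap strips.

    Each 4-neighbour link yields the constraint e_j - e_i = measured shift,
    where e_k is tile k's offset correction; all corrections are solved
    jointly by least squares with tile 0 (or each connected component's
    lowest-index tile) anchored at zero. Links whose correlation peak quality
    falls below ``q_min`` are dropped from the solve.
    """
    n = len(layout.tiles)
    nominal = np.round(layout.nominal_px).astype(int)
    links: list[Link] = []
    for i, j in _neighbour_pairs(layout):
        si, sj = layout.tiles[i].shape, layout.tiles[j].shape
        r_lo, c_lo, r_hi, c_hi = _overlap_rect(nominal[i], si, nominal[j], sj)
        strip_i = layout.tiles[i].pixels[
            r_lo - nominal[i][0] : r_hi - nominal[i][0],
            c_lo - nominal[i][1] : c_hi - nominal[i][1],
        ]
        strip_j = layout.tiles[j].pixels[
            r_lo - nominal[j][0] : r_hi - nominal[j][0],
            c_lo - nominal[j][1] : c_hi - nominal[j][1],
        ]
        try:
            s = phase_correlate(strip_i, strip_j)
        except ValueError:
            warnings.warn(f"link ({i},{j}): no spectral content, dropped")
            links.append(Link(i, j, Shift(0.0, 0.0, 0.0), used=False))
            continue
        used = s.peak_quality >= q_min
        if not used:
            warnings.warn(
                f"link ({i},{j}): peak quality {s.peak_quality:.3g} < {q_min}, dropped"
            )
        links.append(Link(i, j, s, used=used))

    used_links = [lk for lk in links if lk.used]

    # connected components over used links
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for lk in used_links:
        ra, rb = find(lk.i), find(lk.j)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    anchors = sorted({find(k) for k in range(n)})
    if len(anchors) > 1:
        warnings.warn(
            f"mosaic link graph has {len(anchors)} components; "
            "each anchored at its own nominal position"
        )

    corrections = np.zeros((n, 2))
    for axis in range(2):
        rows = []
        rhs = []
        for lk in used_links:
            row = np.zeros(n)
            row[lk.j] += 1.0
            row[lk.i] -= 1.0
            rows.append(row)
            rhs.append(lk.shift.dy if axis == 0 else lk.shift.dx)
        for a in anchors:
            row = np.zeros(n)
            row[a] = 1.0
            rows.append(row)
            rhs.append(0.0)
        A = np.asarray(rows)
        sol, *_ = np.linalg.lstsq(A, np.asarray(rhs), rcond=None)
        corrections[:, axis] = sol

    return MosaicLayout(
        tiles=layout.tiles,
        nominal_px=layout.nominal_px,
        refined_px=layout.nominal_px + corrections,
        overlap_frac=layout.overlap_frac,
        links=links,
    )


def _feather_weights(layout: MosaicLayout) -> list[np.ndarray]:
    """Separable linear ramps: 0 at the tile border rising to 1 at distance
    equal to the measured overlap with the neighbour on that side (floor 8 px),
    with a tiny positive floor so single-coverage pixels stay defined."""
    offsets = layout.offsets
    n = len(layout.tiles)
    # per tile: ramp width on (top, bottom, left, right)
    ramps = np.zeros((n, 4))
    for i, j in _neighbour_pairs(layout):
        si, sj = layout.tiles[i].shape, layout.tiles[j].shape
        r_lo, c_lo, r_hi, c_hi = _overlap_rect(offsets[i], si, offsets[j], sj)
        h, w = r_hi - r_lo, c_hi - c_lo
        if h <= 0 or w <= 0:
            continue
        if h < w:  # vertical neighbours share a horizontal strip
            if offsets[i][0] < offsets[j][0]:
                ramps[i, 1] = max(ramps[i, 1], h)
                ramps[j, 0] = max(ramps[j, 0], h)
            else:
                ramps[i, 0] = max(ramps[i, 0], h)
                ramps[j, 1] = max(ramps[j, 1], h)
        else:
            if offsets[i][1] < offsets[j][1]:
                ramps[i, 3] = max(ramps[i, 3], w)
                ramps[j, 2] = max(ramps[j, 2], w)
            else:
                ramps[i, 2] = max(ramps[i, 2], w)
                ramps[j, 3] = max(ramps[j, 3], w)

    weights = []
    for k, tile in enumerate(layout.tiles):
        h, w = tile.shape
        top, bottom, left, right = ramps[k]
        wy = np.ones(h)
        wx = np.ones(w)
        y = np.arange(h) + 0.5
        x = np.arange(w) + 0.5
        if top > 0:
            t = max(top, FEATHER_FLOOR_PX)
            wy = np.minimum(wy, y / t)
        if bottom > 0:
            b = max(bottom, FEATHER_FLOOR_PX)
            wy = np.minimum(wy, (h - y) / b)
        if left > 0:
            l = max(left, FEATHER_FLOOR_PX)
            wx = np.minimum(wx, x / l)
        if right > 0:
            r = max(right, FEATHER_FLOOR_PX)
            wx = np.minimum(wx, (w - x) / r)
        weights.append(
            np.clip(wy[:, None] * wx[None, :], _W_EPS, 1.0)
        )
    return weights


def blend(
    layout: MosaicLayout, fill_value: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Feathered weighted-average stitch.

    Returns ``(canvas, weight_map)`` where canvas is float32 and pixels with
    zero total weight hold ``fill_value``. Fractional offsets are honoured by
    bicubic resampling of the tile before placement.
    """
    # snap away float dust so the canvas extent is translation-invariant
    offsets = np.round(layout.offsets - layout.offsets.min(axis=0), 6)
    shapes = np.array([t.shape for t in layout.tiles])
    extent = np.ceil(offsets + shapes).astype(int)
    H, W = extent.max(axis=0)
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))
    feathers = _feather_weights(layout)
    for tile, off, fw in zip(layout.tiles, offsets, feathers):
        base = np.floor(off).astype(int)
        frac = off - base
        img = tile.pixels.astype(float)
        if np.any(frac > 1e-9):
            img = scipy.ndimage.shift(img, frac, order=3, mode="nearest")
        h, w = img.shape
        acc[base[0] : base[0] + h, base[1] : base[1] + w] += img * fw
        wacc[base[0] : base[0] + h, base[1] : base[1] + w] += fw
    out = np.full((H, W), float(fill_value))
    good = wacc > 0
    out[good] = acc[good] / wacc[good]
    return out.astype(np.float32), wacc
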