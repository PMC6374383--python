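"""Mosaic tile stitching with correlation-based offset refinement.

Large sections are acquired as a grid of overlapping image tiles (10%
nominal overlap). Stitching is translation-only: tiles come from one
motorized scan of one section, so no per-tile rotation is modelled. Each
tile's placement is refined against its left and top neighbors by
maximizing normalized cross-correlation of the overlap strip, with
quadratic sub-pixel peak interpolation; conflicting neighbor estimates are
resolved by a confidence-weighted average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import quantize
from .section import SectionImage

log = logging.getLogger(__name__)

MIN_OVERLAP_PX = 8


@dataclass
class TileLayout:
    """Placement of a row-major tile grid: nominal and refined origins (x, y) px."""

    grid: tuple[int, int]
    nominal_origins: list[tuple[float, float]]
    overlap_fraction: float = 0.10
    refined_origins: list[tuple[float, float]] | None = None

    @property
    def origins(self) -> list[tuple[float, float]]:
        return self.refined_origins or self.nominal_origins


def nominal_layout(
    grid: tuple[int, int],
    tile_shape: tuple[int, int],
    overlap_fraction: float = 0.10,
) -> TileLayout:
    """Nominal row-major origins: stride = tile size x (1 - overlap)."""
    rows, cols = grid
    th, tw = tile_shape
    origins = [
        (round(j * tw * (1.0 - overlap_fraction)), round(i * th * (1.0 - overlap_fraction)))
        for i in range(rows)
        for j in range(cols)
    ]
    return TileLayout(grid=grid, nominal_origins=origins, overlap_fraction=overlap_fraction)


def _as_plane(tile: np.ndarray) -> np.ndarray:
    """Reduce a (C, h, w) tile to a single correlation plane (first channel)."""
    t = np.asarray(tile, dtype=float)
    return t[0] if t.ndim == 3 else t


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.dot(a, b) / (na * nb))


def _overlap_corr(a: np.ndarray, b: np.ndarray, dx: int, dy: int) -> float:
    """NCC of the overlap of b placed at integer offset (dx, dy) in a's frame."""
    ha, wa = a.shape
    hb, wb = b.shape
    ax0, ax1 = max(dx, 0), min(dx + wb, wa)
    ay0, ay1 = max(dy, 0), min(dy + hb, ha)
    if ax1 - ax0 < MIN_OVERLAP_PX or ay1 - ay0 < MIN_OVERLAP_PX:
        return np.nan
    pa = a[ay0:ay1, ax0:ax1]
    pb = b[ay0 - dy : ay1 - dy, ax0 - dx : ax1 - dx]
    return _ncc(pa, pb)


def _parabolic(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2 * c0 + cp
    if denom >= 0:  # not a peak
        return 0.0
    delta = 0.5 * (cm - cp) / denom
    return float(np.clip(delta, -0.5, 0.5))


def estimate_offset(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    nominal_offset: tuple[float, float],
    search_radius: int = 5,
) -> tuple[tuple[float, float], float]:
    """Refine the translation of tile_b relative to tile_a.

    Searches integer offsets within ``search_radius`` of the nominal
    offset, maximizing normalized cross-correlation of the overlap strip,
    then refines to sub-pixel precision by quadratic interpolation of the
    correlation peak. Returns ``((dx, dy), confidence)`` with confidence
    the peak correlation in [-1, 1]. Flat (zero-variance) overlap returns
    the nominal offset with confidence 0.
    """
    a = _as_plane(tile_a)
    b = _as_plane(tile_b)
    nx, ny = int(round(nominal_offset[0])), int(round(nominal_offset[1]))
    r = int(search_radius)
    dxs = np.arange(nx - r, nx + r + 1)
    dys = np.arange(ny - r, ny + r + 1)
    corr = np.full((len(dys), len(dxs)), np.nan)
    for iy, dy in enumerate(dys):
        for ix, dx in enumerate(dxs):
            corr[iy, ix] = _overlap_corr(a, b, int(dx), int(dy))
    if np.all(np.isnan(corr)):
        warnings.warn(
            "overlap strip has zero variance or insufficient overlap; "
            "keeping nominal tile offset",
            stacklevel=2,
        )
        return (float(nominal_offset[0]), float(nominal_offset[1])), 0.0
    # low-texture strips can tie at the correlation ceiling for several
    # offsets; a vanishing distance penalty prefers the stage position
    dist2 = (dxs[None, :] - nominal_offset[0]) ** 2 + (
        dys[:, None] - nominal_offset[1]
    ) ** 2
    iy, ix = np.unravel_index(np.nanargmax(corr - 1e-6 * dist2), corr.shape)
    best = corr[iy, ix]
    dx, dy = float(dxs[ix]), float(dys[iy])
    # sub-pixel: 1-D parabola through the peak along each axis
    if 0 < ix < len(dxs) - 1 and np.isfinite(corr[iy, ix - 1]) and np.isfinite(corr[iy, ix + 1]):
        dx += _parabolic(corr[iy, ix - 1], best, corr[iy, ix + 1])
    if 0 < iy < len(dys) - 1 and np.isfinite(corr[iy - 1, ix]) and np.isfinite(corr[iy + 1, ix]):
        dy += _parabolic(corr[iy - 1, ix], best, corr[iy + 1, ix])
    return (dx, dy), float(best)


def refine_layout(
    tiles: list[np.ndarray],
    layout: TileLayout,
    search_radius: int = 5,
) -> TileLayout:
    """Refine all tile origins against left and top neighbors.

    Tiles are placed row-major; tile (0, 0) is pinned at its nominal
    origin. Each other tile receives a position estimate from its left and
    from its top neighbor (where present); the estimates are combined by a
    confidence-weighted average, and the result is clamped to within
    ``search_radius`` of the nominal origin.
    """
    rows, cols = layout.grid
    if len(tiles) != rows * cols:
        raise ValueError(f"{len(tiles)} tiles for a {rows}x{cols} grid")
    nominal = [np.array(o, dtype=float) for o in layout.nominal_origins]
    refined: list[np.ndarray] = [nominal[0].copy()]
    for idx in range(1, rows * cols):
        i, j = divmod(idx, cols)
        estimates, weights = [], []
        for ni, nj in ((i, j - 1), (i - 1, j)):
            if ni < 0 or nj < 0:
                continue
            nidx = ni * cols + nj
            rel_nominal = nominal[idx] - nominal[nidx]
            (dx, dy), conf = estimate_offset(
                tiles[nidx], tiles[idx], tuple(rel_nominal), search_radius
            )
            estimates.append(refined[nidx] + np.array([dx, dy]))
            weights.append(max(conf, 0.0))
        if not estimates or sum(weights) == 0:
            pos = nominal[idx].copy()
        else:
            w = np.array(weights)
            pos = np.average(np.stack(estimates), axis=0, weights=w)
        pos = np.clip(pos, nominal[idx] - search_radius, nominal[idx] + search_radius)
        refined.append(pos)
    return TileLayout(
        grid=layout.grid,
        nominal_origins=layout.nominal_origins,
        overlap_fraction=layout.overlap_fraction,
        refined_origins=[(float(p[0]), float(p[1])) for p in refined],
    )


def _feather_weight(h: int, w: int) -> np.ndarray:
    """Integer-valued ramp: distance to the nearest tile edge + 1."""
    iy = np.minimum(np.arange(h), np.arange(h)[::-1]) + 1
    ix = np.minimum(np.arange(w), np.arange(w)[::-1]) + 1
    return np.minimum(iy[:, None], ix[None, :]).astype(float)


def stitch(
    tiles: list[np.ndarray],
    layout: TileLayout,
    blend: str = "feather",
) -> np.ndarray:
    """Assemble tiles into one section image on the union bounding box.

    ``blend="feather"`` combines overlaps with a linear distance-to-edge
    ramp (weights sum to 1 after normalization, so identical content
    reproduces exactly); ``blend="overwrite"`` lets the last tile placed
    win. Intensities are widened to float during blending and re-quantized
    to the tile dtype at the end. A tile whose bounding box touches no
    previously placed tile makes the mosaic disconnected and raises.
    """
    if blend not in ("feather", "overwrite"):
        raise ValueError(f"unknown blend mode {blend!r}")
    if not tiles:
        raise ValueError("no tiles to stitch")
    arrs = [np.asarray(t) for t in tiles]
    multi = arrs[0].ndim == 3
    dtype = arrs[0].dtype
    planes = [a if multi else a[None] for a in arrs]
    nch = planes[0].shape[0]
    origins = [(int(round(x)), int(round(y))) for x, y in layout.origins]
    x0 = min(o[0] for o in origins)
    y0 = min(o[1] for o in origins)
    x1 = max(o[0] + p.shape[2] for o, p in zip(origins, planes))
    y1 = max(o[1] + p.shape[1] for o, p in zip(origins, planes))
    H, W = y1 - y0, x1 - x0

    # connectivity check on bounding boxes
    boxes = [
        (ox - x0, oy - y0, ox - x0 + p.shape[2], oy - y0 + p.shape[1])
        for (ox, oy), p in zip(origins, planes)
    ]
    placed = [0]
    remaining = list(range(1, len(boxes)))
    while remaining:
        progressed = False
        for k in list(remaining):
            bx0, by0, bx1, by1 = boxes[k]
            for p in placed:
                px0, py0, px1, py1 = boxes[p]
                if bx0 < px1 and px0 < bx1 and by0 < py1 and py0 < by1:
                    placed.append(k)
                    remaining.remove(k)
                    progressed = True
                    break
        if not progressed:
            raise ValueError(
                f"tile(s) {remaining} overlap no placed tile: mosaic is disconnected"
            )

    acc = np.zeros((nch, H, W))
    wsum = np.zeros((H, W))
    for (ox, oy), p in zip(origins, planes):
        h, w = p.shape[1:]
        sy, sx = oy - y0, ox - x0
        if blend == "overwrite":
            acc[:, sy : sy + h, sx : sx + w] = p.astype(float)
            wsum[sy : sy + h, sx : sx + w] = 1.0
        else:
            wt = _feather_weight(h, w)
            acc[:, sy : sy + h, sx : sx + w] += p.astype(float) * wt
            wsum[sy : sy + h, sx : sx + w] += wt
    out = np.zeros_like(acc)
    mask = wsum > 0
    if blend == "feather":
        out[:, mask] = acc[:, mask] / wsum[mask]
    else:
        out[:, mask] = acc[:, mask]
    if np.issubdtype(dtype, np.integer):
        bit_depth = 8 * dtype.itemsize
        result = quantize(out, bit_depth).astype(dtype)
    else:
        result = out.astype(dtype)
    return result if multi else result[0]


def stitch_mosaic(
    tiles: list[np.ndarray],
    grid: tuple[int, int],
    overlap_fraction: float = 0.10,
    blend: str = "feather",
    refine: bool = True,
    search_radius: int = 5,
    pixel_size: float | None = None,
    thickness: float | None = None,
    channel_names=None,
    index: int = 0,
) -> tuple[SectionImage, TileLayout]:
    """High-level stitch: build the nominal grid layout, refine, blend."""
    plane = np.asarray(tiles[0])
    tile_shape = plane.shape[-2:]
    layout = nominal_layout(grid, tile_shape, overlap_fraction)
    if refine and len(tiles) > 1:
        layout = refine_layout(tiles, layout, search_radius=search_radius)
    data = stitch(tiles, layout, blend=blend)
    section = SectionImage(
        data=data,
        channel_names=list(channel_names) if channel_names else [],
        index=index,
        pixel_size=pixel_size,
        thickness=thickness,
    )
    return section, layout
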