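"""Synthetic serial-section phantom with full ground truth.

The phantom emulates the acquisition chain of immunofluorescence
tomography: a 3-D tissue block containing ellipsoidal (here spherical)
nuclei is physically sectioned into 2 µm slabs, each slab is imaged as a
2-D widefield raster at 0.44 µm pixel pitch, sections land on the slide
with a small random in-plane misplacement, and large sections may be
acquired as a mosaic of overlapping tiles (10% nominal overlap).

Nuclei carry an H2B-GFP label diluted by cell division: a cell that has
divided ``k`` times since the pulse retains ``0.5**k`` of the initial
fluorescence intensity, so retained intensity indexes quiescence
(label-retaining cells). The DAPI channel marks every nucleus at full
intensity and is the registration channel downstream.

Everything that was applied — cell centroids, radii, division counts,
true intensities, per-section rigid transforms, true tile origins — is
recorded in :class:`PhantomTruth` so every pipeline stage can be checked
against ground truth.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .section import SectionImage
from .transforms import RigidTransform2D, warp_image

TRUTH_NAME = "truth.json"


def quantize(values: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Round-half-up then clip to the unsigned integer range of bit_depth."""
    full = (1 << bit_depth) - 1
    q = np.clip(np.floor(np.asarray(values, dtype=float) + 0.5), 0, full)
    return q.astype(np.uint8 if bit_depth <= 8 else np.uint16)


def dilution_intensity(initial: float, divisions: int) -> float:
    """GFP intensity after ``divisions`` cell divisions.

    The label halves with every division: ``initial * 0.5**divisions``.
    Returned real-valued; quantization to the image bit depth happens at
    rasterization.
    """
    if initial < 0:
        raise ValueError(f"initial intensity must be >= 0, got {initial}")
    if divisions != int(divisions) or divisions < 0:
        raise ValueError(f"divisions must be a non-negative integer, got {divisions}")
    return float(initial) * 0.5 ** int(divisions)


@dataclass
class PhantomConfig:
    """Generation parameters for one synthetic serial-section dataset.

    Defaults mirror the acquisition they emulate: 2 µm sections, 0.44 µm
    pixels, 10% tile overlap, 8-bit intensities with a full-scale (255)
    initial GFP label.
    """

    tissue_extent: tuple[float, float, float] = (60.0, 60.0, 40.0)  # (x, y, z) µm
    n_cells: int = 60
    nucleus_radius_range: tuple[float, float] = (3.0, 5.0)  # µm
    section_thickness: float = 2.0  # µm
    pixel_size: float = 0.44  # µm
    divisions_max: int = 8  # divisions per cell ~ uniform integer 0..divisions_max
    initial_intensity: float = 255.0
    dapi_intensity: float = 255.0
    background_level: float = 0.0
    noise_sd: float = 0.0
    misalignment_range: tuple[float, float, float] = (0.0, 0.0, 0.0)  # |tx|,|ty| px; |θ| deg
    tile_grid: tuple[int, int] | None = None  # (rows, cols)
    tile_overlap_fraction: float = 0.10
    tile_jitter_px: int = 0
    min_separation: float = 1.5  # µm gap enforced between nucleus surfaces
    enforce_separation: bool = True  # False: dense tissue, nuclei may touch
    field_margin: float = 0.0  # µm of empty field imaged around the tissue
    z_overhang: float = 0.0  # µm of tissue beyond the sectioned range (each side)
    stratify_z: bool = False  # spread nuclei evenly along z (volume-excluding tissue)
    bit_depth: int = 8
    seed: int = 0

    def validate(self) -> None:
        if any(e <= 0 for e in self.tissue_extent):
            raise ValueError("tissue_extent must be positive in all axes")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0 < self.tile_overlap_fraction < 1:
            raise ValueError("tile_overlap_fraction must be in (0, 1)")
        rmin, rmax = self.nucleus_radius_range
        if not 0 < rmin <= rmax:
            raise ValueError("nucleus_radius_range must satisfy 0 < min <= max")
        if rmax >= min(self.tissue_extent) / 2:
            raise ValueError("nucleus radii must be < min(tissue_extent)/2")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.divisions_max < 0:
            raise ValueError("divisions_max must be >= 0")

    @property
    def n_sections(self) -> int:
        return math.ceil(self.tissue_extent[2] / self.section_thickness)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["tissue_extent"] = list(self.tissue_extent)
        d["nucleus_radius_range"] = list(self.nucleus_radius_range)
        d["misalignment_range"] = list(self.misalignment_range)
        d["tile_grid"] = list(self.tile_grid) if self.tile_grid else None
        return d


@dataclass
class Cell:
    id: int
    centroid_um: tuple[float, float, float]  # (x, y, z)
    radius_um: float
    division_count: int
    true_intensity: float


@dataclass
class PhantomTruth:
    """Everything the generator applied, for downstream verification."""

    cells: list[Cell]
    section_transforms: list[RigidTransform2D]
    tile_offsets: list[list[tuple[int, int]]] | None
    n_sections: int
    config: PhantomConfig

    def save(self, path) -> None:
        payload = {
            "n_sections": self.n_sections,
            "cells": [
                {
                    "id": c.id,
                    "centroid_um": list(c.centroid_um),
                    "radius_um": c.radius_um,
                    "division_count": c.division_count,
                    "true_intensity": c.true_intensity,
                }
                for c in self.cells
            ],
            "section_transforms": [t.as_dict() for t in self.section_transforms],
            "tile_offsets": self.tile_offsets,
            "config": self.config.as_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "PhantomTruth":
        d = json.loads(Path(path).read_text())
        cfg = d.get("config", {})
        for key in ("tissue_extent", "nucleus_radius_range", "misalignment_range"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        if cfg.get("tile_grid"):
            cfg["tile_grid"] = tuple(cfg["tile_grid"])
        return cls(
            cells=[
                Cell(
                    id=c["id"],
                    centroid_um=tuple(c["centroid_um"]),
                    radius_um=c["radius_um"],
                    division_count=c["division_count"],
                    true_intensity=c["true_intensity"],
                )
                for c in d["cells"]
            ],
            section_transforms=[
                RigidTransform2D.from_dict(t) for t in d["section_transforms"]
            ],
            tile_offsets=[
                [tuple(o) for o in sec] for sec in d["tile_offsets"]
            ]
            if d.get("tile_offsets")
            else None,
            n_sections=d["n_sections"],
            config=PhantomConfig(**cfg) if cfg else PhantomConfig(),
        )


def _separated(c_new, r_new, cells, min_sep, thickness):
    """True if the new nucleus cannot merge with any accepted one after
    slab projection.

    Two nuclei stay distinct 3-D objects when either their in-plane (xy)
    circles are separated by min_sep, or a full empty slab lies between
    their z-supports (max-projection smears each nucleus across every slab
    it touches, and 26-connectivity bridges adjacent slabs).
    """
    x, y, z = c_new
    for c in cells:
        cx, cy, cz = c.centroid_um
        xy_gap = math.hypot(x - cx, y - cy) - r_new - c.radius_um
        z_gap = abs(z - cz) - r_new - c.radius_um
        if xy_gap <= min_sep and z_gap <= 2 * thickness + min_sep:
            return False
    return True


def _sample_cells(config: PhantomConfig, rng: np.random.Generator) -> list[Cell]:
    ex, ey, ez = config.tissue_extent
    rmin, rmax = config.nucleus_radius_range
    n = config.n_cells
    cells: list[Cell] = []
    # with z_overhang the tissue continues past the sectioned range, so the
    # first and last slabs are as densely populated as the middle
    strata: list[tuple[float, float]] | None = None
    if config.stratify_z and n > 0:
        # real tissue is more even than Poisson (cells exclude volume):
        # stratified z keeps every slab populated
        zlo, zhi = -config.z_overhang, ez + config.z_overhang
        width = (zhi - zlo) / n
        order = rng.permutation(n)
        strata = [(zlo + order[i] * width, width) for i in range(n)]
    attempts = 0
    max_attempts = max(10_000, 5_000 * n)
    while len(cells) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-touching nuclei in "
                f"extent {config.tissue_extent}; placed {len(cells)}"
            )
        attempts += 1
        r = float(rng.uniform(rmin, rmax))
        if strata is not None:
            z0, width = strata[len(cells)]
            z = z0 + float(rng.uniform(0.0, width))
        elif config.z_overhang:
            z = float(rng.uniform(-config.z_overhang, ez + config.z_overhang))
        else:
            z = float(rng.uniform(r, ez - r))
        c = (
            float(rng.uniform(r, ex - r)),
            float(rng.uniform(r, ey - r)),
            z,
        )
        if config.enforce_separation and not _separated(
            c, r, cells, config.min_separation, config.section_thickness
        ):
            continue
        k = int(rng.integers(0, config.divisions_max + 1))
        cells.append(
            Cell(
                id=len(cells),
                centroid_um=c,
                radius_um=r,
                division_count=k,
                true_intensity=dilution_intensity(config.initial_intensity, k),
            )
        )
    return cells


def _rasterize_section(
    cells: list[Cell],
    z0: float,
    z1: float,
    shape: tuple[int, int],
    pixel_size: float,
    dapi_intensity: float,
) -> np.ndarray:
    """Slab maximum-intensity projection of the analytic nucleus profiles.

    Each nucleus is a solid sphere with a soft linear 1-px edge falloff.
    With 2 µm sections every nucleus lies within the focal plane, so the
    widefield image of a slab is modelled as the max projection of the
    profile through the slab: at in-plane distance d from the center the
    projected profile is governed by the largest in-plane radius the sphere
    attains inside the slab.
    """
    ny, nx = shape
    out = np.zeros((2, ny, nx))  # channels: DAPI, GFP
    for cell in cells:
        cx, cy, cz = cell.centroid_um
        r = cell.radius_um
        if cz + r <= z0 or cz - r >= z1:
            continue
        dz = 0.0 if z0 <= cz <= z1 else min(abs(cz - z0), abs(cz - z1))
        r_eff = math.sqrt(max(r * r - dz * dz, 0.0))
        if r_eff <= 0:
            continue
        j0 = max(int(math.floor((cx - r_eff) / pixel_size)) - 1, 0)
        j1 = min(int(math.ceil((cx + r_eff) / pixel_size)) + 2, nx)
        i0 = max(int(math.floor((cy - r_eff) / pixel_size)) - 1, 0)
        i1 = min(int(math.ceil((cy + r_eff) / pixel_size)) + 2, ny)
        if j0 >= j1 or i0 >= i1:
            continue
        xs = np.arange(j0, j1) * pixel_size - cx
        ys = np.arange(i0, i1) * pixel_size - cy
        d = np.hypot(xs[None, :], ys[:, None])
        f = np.clip((r_eff - d) / pixel_size, 0.0, 1.0)
        np.maximum(out[0, i0:i1, j0:j1], dapi_intensity * f, out=out[0, i0:i1, j0:j1])
        np.maximum(
            out[1, i0:i1, j0:j1], cell.true_intensity * f, out=out[1, i0:i1, j0:j1]
        )
    return out


def generate_phantom(
    config: PhantomConfig,
) -> tuple[list[SectionImage], PhantomTruth]:
    """Generate an ordered serial-section dataset plus its ground truth.

    Returns ``ceil(extent_z / thickness)`` sections, each a two-channel
    (DAPI, GFP) raster with the section's true rigid misplacement applied,
    background and Gaussian noise added, quantized to the configured bit
    depth. Section 0 is never perturbed and serves as the alignment
    reference. Same seed, same output, bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ex, ey, ez = config.tissue_extent
    t = config.section_thickness
    if ez < t:
        warnings.warn(
            f"tissue extent z ({ez} um) is thinner than one section ({t} um); "
            "emitting a single section",
            stacklevel=2,
        )
    n_sections = config.n_sections
    cells = _sample_cells(config, rng)
    if config.field_margin:
        # the slide is imaged with empty field around the tissue, so a
        # misplaced section never pushes tissue out of frame
        m = config.field_margin
        cells = [
            Cell(
                id=c.id,
                centroid_um=(c.centroid_um[0] + m, c.centroid_um[1] + m, c.centroid_um[2]),
                radius_um=c.radius_um,
                division_count=c.division_count,
                true_intensity=c.true_intensity,
            )
            for c in cells
        ]
        ex, ey = ex + 2 * m, ey + 2 * m
    shape = (math.ceil(ey / config.pixel_size), math.ceil(ex / config.pixel_size))

    mtx, mty, mtheta = config.misalignment_range
    transforms = [RigidTransform2D(0.0, 0.0, 0.0)]
    for _ in range(1, n_sections):
        transforms.append(
            RigidTransform2D(
                tx=float(rng.uniform(-mtx, mtx)) if mtx else 0.0,
                ty=float(rng.uniform(-mty, mty)) if mty else 0.0,
                theta=float(rng.uniform(-mtheta, mtheta)) if mtheta else 0.0,
            )
        )

    sections = []
    for s in range(n_sections):
        clean = _rasterize_section(
            cells, s * t, (s + 1) * t, shape, config.pixel_size,
            config.dapi_intensity,
        )
        if not transforms[s].is_identity():
            clean = warp_image(clean, transforms[s])
        img = clean + config.background_level
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        sections.append(
            SectionImage(
                data=quantize(img, config.bit_depth),
                channel_names=["DAPI", "GFP"],
                index=s,
                pixel_size=config.pixel_size,
                thickness=t,
            )
        )

    truth = PhantomTruth(
        cells=cells,
        section_transforms=transforms,
        tile_offsets=None,
        n_sections=n_sections,
        config=config,
    )
    return sections, truth


def _tile_starts(extent: int, n: int, size: int, overlap: float) -> list[int]:
    if n == 1:
        return [0]
    return [min(round(j * size * (1.0 - overlap)), extent - size) for j in range(n)]


def tile_size(extent: int, n: int, overlap: float) -> int:
    """Smallest integer tile size covering ``extent`` with n tiles at the
    given fractional overlap: the least w with n*w - (n-1)*overlap*w >= extent."""
    return math.ceil(extent / (n - (n - 1) * overlap))


def tile_section(
    section: SectionImage,
    grid: tuple[int, int],
    overlap_fraction: float = 0.10,
    jitter_px: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], list[tuple[int, int]], list[tuple[int, int]]]:
    """Cut a section into a row-major mosaic of overlapping tiles.

    Returns ``(tiles, nominal_origins, true_origins)`` with origins as
    (x, y) pixel coordinates of each tile's top-left corner. Tiles are
    crops of the section at the *true* origins; with ``jitter_px`` > 0 the
    true origins deviate from the nominal grid by a bounded uniform integer
    perturbation (tile (0, 0) stays fixed), emulating stage positioning
    error that stitching must recover.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError(f"grid must be >= (1, 1), got {grid}")
    if not 0 < overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in (0, 1)")
    h, w = section.shape
    tw = tile_size(w, cols, overlap_fraction)
    th = tile_size(h, rows, overlap_fraction)
    if tw < 2 or th < 2:
        raise ValueError(f"tile size {th}x{tw} too small (< 2 px)")
    xs = _tile_starts(w, cols, tw, overlap_fraction)
    ys = _tile_starts(h, rows, th, overlap_fraction)
    if rng is None:
        rng = np.random.default_rng(0)
    tiles, nominal, true = [], [], []
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            nominal.append((x0, y0))
            if jitter_px and not (i == 0 and j == 0):
                jx = int(rng.integers(-jitter_px, jitter_px + 1))
                jy = int(rng.integers(-jitter_px, jitter_px + 1))
                tx0 = min(max(x0 + jx, 0), w - tw)
                ty0 = min(max(y0 + jy, 0), h - th)
            else:
                tx0, ty0 = x0, y0
            true.append((tx0, ty0))
            tiles.append(section.data[:, ty0 : ty0 + th, tx0 : tx0 + tw].copy())
    return tiles, nominal, true


def expected_counts_from_truth(
    truth: PhantomTruth,
    bin_edges: tuple = (0, 100, 200, 255),
    lrc_floor: float = 1.0,
) -> dict:
    """Brute-force sub-population counts straight from the truth table.

    Applies the dilution law (already stored per cell), the generator's
    8-bit quantization, the LRC positivity floor and the intensity bins to
    every cell — no image processing involved. Serves as the independent
    oracle for the segmentation/quantification chain. Cells lying wholly
    outside the sectioned z-range (possible with ``z_overhang``) are never
    imaged and are excluded.
    """
    z_max = truth.n_sections * truth.config.section_thickness
    lo, mid, hi = 0, 0, 0
    lrc = 0
    total = 0
    for cell in truth.cells:
        cz = cell.centroid_um[2]
        if cz + cell.radius_um <= 0 or cz - cell.radius_um >= z_max:
            continue
        total += 1
        q = float(quantize(np.array([cell.true_intensity]), truth.config.bit_depth)[0])
        if q < lrc_floor:
            continue
        lrc += 1
        if q < bin_edges[1]:
            lo += 1
        elif q < bin_edges[2]:
            mid += 1
        else:
            hi += 1
    return {
        "total_nuclei": total,
        "lrc_total": lrc,
        "per_bin": (lo, mid, hi),
    }
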