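"""Reference benchmarks exercising the full pipeline on phantoms.

Each benchmark generates its inputs from scratch with a caller-supplied
seed, runs the relevant pipeline stage, and measures recovery against the
phantom ground truth. The study conditions (problem sizes, noise and
misplacement levels) are fixed here so the same numbers are reproducible
from the test suite, the acceptance script and interactive use.
"""

from __future__ import annotations

import numpy as np

from .mosaic import TileLayout, stitch, stitch_mosaic
from .phantom import (
    PhantomConfig,
    expected_counts_from_truth,
    generate_phantom,
    tile_section,
)
from .quantify import CellCountReport, classify_bin, count_subpopulations, segment_nuclei
from .register import align_stack, fuse_reprobe
from .section import SectionImage
from .transforms import RigidTransform2D, compose, warp_image
from .volume import Volume, assemble, slide_capacity


def worked_examples() -> dict:
    """Closed-form checks: binning percentages, stack geometry, re-probe fusion.

    Reference figures: a hair-follicle reconstruction with 654 DAPI nuclei
    of which 91 are label-retaining (20 high / 31 mid / 40 low), serial
    stacks of 379, 533, 97 and 170 sections cut at 2 µm, slides carrying
    3 ribbons of 25 sections, and two 3-channel imaging rounds sharing
    DAPI fused into one 5-channel section.
    """
    report = CellCountReport.from_counts(654, per_bin=(40, 31, 20))
    depths = {
        n: Volume(
            data=np.zeros((1, n, 1, 1), dtype=np.uint8),
            voxel_size=(0.44, 0.44, 2.0),
        ).z_extent_um
        for n in (379, 533, 97, 170)
    }

    cfg = PhantomConfig(
        tissue_extent=(40, 40, 12), n_cells=10, nucleus_radius_range=(2.5, 3.5),
        seed=1,
    )
    sections, _ = generate_phantom(cfg)
    base = sections[3]
    r1 = SectionImage(
        np.stack([base.data[0], base.data[1], base.data[1] // 2]),
        ["DAPI", "K5", "PPARg"], pixel_size=0.44, thickness=2.0,
    )
    shifted = np.clip(
        np.floor(warp_image(r1.data, RigidTransform2D(4, 4, 0)) + 0.5), 0, 255
    ).astype(np.uint8)
    r2 = SectionImage(shifted, ["DAPI", "K6", "Ki67"], pixel_size=0.44, thickness=2.0)
    fused, _ = fuse_reprobe(r1, r2)

    return {
        "lrc_total": report.lrc_total,
        "per_bin_pct": report.per_bin_pct,  # (low, mid, high)
        "z_depth_um": depths,
        "slide_capacity_um": slide_capacity(3, 25, 2.0),
        "fused_channels": fused.n_channels,
    }


def registration_phantom_config(seed: int) -> PhantomConfig:
    """Study conditions for the registration benchmark.

    50 sections (100 µm at 2 µm), 80 nuclei, per-section misplacement up
    to ±15 px and ±5°, additive noise at 5% of the 8-bit range. The tissue
    is a dense 72 µm-wide core imaged with 10 µm of empty field around it
    and continues 6 µm past the sectioned range, with nuclei spread evenly
    along z — every slab is populated, as in real serially sectioned
    tissue.
    """
    return PhantomConfig(
        tissue_extent=(72.0, 72.0, 100.0),
        n_cells=80,
        nucleus_radius_range=(4.5, 6.0),
        misalignment_range=(15.0, 15.0, 5.0),
        noise_sd=12.75,
        enforce_separation=True,
        field_margin=10.0,
        z_overhang=6.0,
        stratify_z=True,
        seed=seed,
    )


def registration_benchmark(seed: int = 0) -> dict:
    """Align the 50-section misaligned phantom and measure recovery errors."""
    cfg = registration_phantom_config(seed)
    sections, truth = generate_phantom(cfg)
    result, _ = align_stack(sections, max_rotation=11.0)
    pair_px, pair_deg = [], []
    for i in range(1, len(sections)):
        true_pair = compose(
            truth.section_transforms[i - 1], truth.section_transforms[i].inverse()
        )
        got = result.pairwise[i]
        pair_px.append(np.hypot(got.tx - true_pair.tx, got.ty - true_pair.ty))
        pair_deg.append(abs(got.theta - true_pair.theta))
    last = result.absolute[-1]
    want = truth.section_transforms[-1].inverse()
    return {
        "n_sections": len(sections),
        "mean_pair_error_px": float(np.mean(pair_px)),
        "mean_pair_error_deg": float(np.mean(pair_deg)),
        "max_pair_error_px": float(np.max(pair_px)),
        "end_stack_error_px": float(np.hypot(last.tx - want.tx, last.ty - want.ty)),
        "end_stack_error_deg": float(abs(last.theta - want.theta)),
        "n_flagged": len(result.flagged),
    }


def stitching_benchmark(seed: int = 0) -> dict:
    """Tile a phantom section at 10% overlap and reassemble it.

    Noise-free 2x2 and 8x8 tilings restitched at their true origins must
    reproduce the section bit-exactly; a jittered 2x2 tiling refined by
    correlation must recover the true origins within 0.5 px.
    """
    # dense tissue so every 10% seam strip carries nucleus texture
    cfg = PhantomConfig(
        tissue_extent=(80.0, 80.0, 16.0), n_cells=120,
        nucleus_radius_range=(2.5, 3.5), enforce_separation=False, seed=seed,
    )
    sections, _ = generate_phantom(cfg)
    section = sections[2]
    out = {}
    for grid in ((2, 2), (8, 8)):
        tiles, _, true = tile_section(section, grid, 0.10)
        layout = TileLayout(grid=grid, nominal_origins=true, overlap_fraction=0.10)
        diff = 0
        for blend in ("overwrite", "feather"):
            restitched = stitch(tiles, layout, blend=blend)
            diff += int(np.count_nonzero(restitched != section.data))
        out[f"mismatched_pixels_{grid[0]}x{grid[1]}"] = diff
    rng = np.random.default_rng(seed + 1)
    tiles, _, true = tile_section(section, (2, 2), 0.10, jitter_px=3, rng=rng)
    _, layout = stitch_mosaic(tiles, (2, 2), 0.10, refine=True, search_radius=6)
    err = np.abs(np.array(layout.refined_origins) - np.array(true, dtype=float))
    out["jitter_recovery_error_px"] = float(err.max())
    return out


def quantification_phantom_config(seed: int) -> PhantomConfig:
    """Study conditions for the counting benchmark: 200 non-touching
    nuclei with 0-8 divisions each, noise-free."""
    return PhantomConfig(
        tissue_extent=(160.0, 160.0, 60.0),
        n_cells=200,
        nucleus_radius_range=(2.5, 4.0),
        divisions_max=8,
        noise_sd=0.0,
        seed=seed,
    )


def quantification_benchmark(seed: int = 0) -> dict:
    """Segment, bin and count a 200-nucleus phantom; compare with the truth table."""
    cfg = quantification_phantom_config(seed)
    sections, truth = generate_phantom(cfg)
    vol = assemble(sections)
    objects = segment_nuclei(vol, "DAPI", threshold=250, min_volume_voxels=5)
    report = count_subpopulations(objects, "GFP", lrc_floor=1.0)
    expected = expected_counts_from_truth(truth)
    bin_oracle_agreement = all(
        classify_bin(v) == ("low" if v < 100 else "mid" if v < 200 else "high")
        for v in range(256)
    )
    return {
        "total_nuclei": report.total_nuclei,
        "lrc_total": report.lrc_total,
        "per_bin": report.per_bin,
        "expected_total_nuclei": expected["total_nuclei"],
        "expected_lrc_total": expected["lrc_total"],
        "expected_per_bin": expected["per_bin"],
        "count_discrepancy": int(
            abs(report.total_nuclei - expected["total_nuclei"])
            + abs(report.lrc_total - expected["lrc_total"])
            + sum(abs(a - b) for a, b in zip(report.per_bin, expected["per_bin"]))
        ),
        "bin_enumeration_agrees": bin_oracle_agreement,
    }
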