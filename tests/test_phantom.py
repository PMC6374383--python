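"""Phantom generator: dilution law, sectioning, tiling, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iftomo.phantom import (
    PhantomConfig,
    dilution_intensity,
    expected_counts_from_truth,
    generate_phantom,
    quantize,
    tile_section,
    tile_size,
)
from iftomo.section import SectionImage


class TestDilution:
    def test_zero_divisions_identity(self):
        assert dilution_intensity(255, 0) == 255

    def test_one_division_halves(self):
        assert dilution_intensity(255, 1) == 127.5

    def test_three_divisions_matches_repeated_halving(self):
        expected = 255.0
        for _ in range(3):
            expected *= 0.5
        assert dilution_intensity(255, 3) == expected == 31.875

    @settings(deadline=None)
    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.integers(0, 40),
    )
    def test_halving_law(self, initial, k):
        assert dilution_intensity(initial, k + 1) == pytest.approx(
            0.5 * dilution_intensity(initial, k)
        )

    @pytest.mark.parametrize("initial,divisions", [(-1, 0), (255, -1), (255, 1.5)])
    def test_invalid_arguments(self, initial, divisions):
        with pytest.raises(ValueError):
            dilution_intensity(initial, divisions)


class TestGeneration:
    def test_section_count_is_ceil_of_depth_over_thickness(self):
        cfg = PhantomConfig(tissue_extent=(20, 20, 20), n_cells=0, section_thickness=2.0)
        sections, truth = generate_phantom(cfg)
        assert len(sections) == truth.n_sections == 10

    def test_thin_tissue_gives_single_section_with_warning(self):
        cfg = PhantomConfig(
            tissue_extent=(20, 20, 1.0), n_cells=0, section_thickness=2.0,
            nucleus_radius_range=(0.2, 0.3),
        )
        with pytest.warns(UserWarning, match="single section"):
            sections, _ = generate_phantom(cfg)
        assert len(sections) == 1

    def test_empty_phantom_is_all_zero(self):
        cfg = PhantomConfig(
            tissue_extent=(20, 20, 8), n_cells=0, background_level=0, noise_sd=0,
            nucleus_radius_range=(2.0, 3.0),
        )
        sections, _ = generate_phantom(cfg)
        assert all(not s.data.any() for s in sections)

    def test_single_cell_one_division_peak_is_128(self):
        """Brightest GFP pixel of a once-divided cell is the 8-bit rounding of 127.5."""
        one_division = dilution_intensity(255, 1)
        assert quantize(np.array([one_division]))[0] == 128
        cfg = PhantomConfig(
            tissue_extent=(30, 30, 12), n_cells=1, nucleus_radius_range=(3.0, 3.0),
            divisions_max=0, initial_intensity=one_division, noise_sd=0, seed=2,
        )
        sections, truth = generate_phantom(cfg)
        assert truth.cells[0].true_intensity == one_division
        assert max(s.data[1].max() for s in sections) == 128

    def test_dapi_presence_matches_slab_intersection_bruteforce(self, small_phantom):
        """A cell is visible in exactly the sections its z-interval intersects."""
        cfg, sections, truth = small_phantom
        t = cfg.section_thickness
        for cell in truth.cells:
            cx, cy, cz = cell.centroid_um
            px = cfg.pixel_size
            j, i = round(cx / px), round(cy / px)
            for s, sec in enumerate(sections):
                z0, z1 = s * t, (s + 1) * t
                intersects = (cz - cell.radius_um) < z1 and (cz + cell.radius_um) > z0
                lit = sec.data[0, i, j] > 0
                assert bool(lit) == intersects, (cell.id, s)

    def test_same_seed_bit_identical(self):
        cfg = PhantomConfig(tissue_extent=(30, 30, 10), n_cells=8, noise_sd=6.0,
                            misalignment_range=(4, 4, 2), seed=13,
                            nucleus_radius_range=(2.0, 3.0))
        a, _ = generate_phantom(cfg)
        b, _ = generate_phantom(cfg)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))

    def test_truth_intensity_respects_dilution_law(self, small_phantom):
        _, _, truth = small_phantom
        for cell in truth.cells:
            assert cell.true_intensity == pytest.approx(
                255.0 * 0.5 ** cell.division_count
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tissue_extent": (0, 10, 10)},
            {"section_thickness": 0},
            {"tile_overlap_fraction": 1.0},
            {"nucleus_radius_range": (5.0, 3.0)},
            {"nucleus_radius_range": (6.0, 6.0), "tissue_extent": (10, 10, 10)},
            {"n_cells": -1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomConfig(**kwargs).validate()


class TestTiling:
    def test_tile_size_solves_covering_inequality(self):
        # smallest integer w with c*w - (c-1)*overlap*w >= W
        for W, c, o in [(100, 2, 0.10), (364, 8, 0.10), (91, 3, 0.25)]:
            w = tile_size(W, c, o)
            assert c * w - (c - 1) * o * w >= W
            assert c * (w - 1) - (c - 1) * o * (w - 1) < W

    def test_two_column_example(self):
        """Width 100, 1x2 grid, 10% overlap: 53-px tiles, second origin at 47."""
        sec = SectionImage(np.zeros((1, 40, 100), dtype=np.uint8))
        tiles, nominal, true = tile_section(sec, (1, 2), 0.10)
        assert tiles[0].shape[-1] == 53
        assert [o[0] for o in nominal] == [0, 47]

    def test_single_tile_equals_section(self):
        data = (np.arange(1 * 20 * 30) % 251).astype(np.uint8).reshape(1, 20, 30)
        sec = SectionImage(data)
        tiles, nominal, true = tile_section(sec, (1, 1), 0.10)
        assert len(tiles) == 1 and nominal == [(0, 0)]
        assert np.array_equal(tiles[0], data)

    def test_reassembly_at_true_origins_is_bit_exact(self, small_phantom):
        _, sections, _ = small_phantom
        sec = sections[4]
        tiles, _, true = tile_section(sec, (2, 3), 0.10)
        canvas = np.zeros_like(sec.data)
        th, tw = tiles[0].shape[-2:]
        for tile, (x0, y0) in zip(tiles, true):
            canvas[:, y0 : y0 + th, x0 : x0 + tw] = tile
        assert np.array_equal(canvas, sec.data)

    def test_jittered_origins_recorded_and_bounded(self, rng):
        sec = SectionImage(np.zeros((1, 120, 120), dtype=np.uint8))
        _, nominal, true = tile_section(sec, (2, 2), 0.10, jitter_px=3, rng=rng)
        assert true[0] == nominal[0]  # anchor tile never jitters
        deltas = np.abs(np.array(true) - np.array(nominal))
        assert deltas.max() <= 3

    def test_tiny_tiles_rejected(self):
        sec = SectionImage(np.zeros((1, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError):
            tile_section(sec, (3, 3), 0.10)


def test_truth_roundtrip_and_oracle(tmp_path, small_phantom):
    from iftomo.phantom import PhantomTruth

    _, _, truth = small_phantom
    truth.save(tmp_path / "truth.json")
    loaded = PhantomTruth.load(tmp_path / "truth.json")
    assert len(loaded.cells) == len(truth.cells)
    assert expected_counts_from_truth(loaded) == expected_counts_from_truth(truth)
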