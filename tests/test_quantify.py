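"""Segmentation, intensity binning and sub-population counting."""

import numpy as np
import pytest

from iftomo.phantom import (
    PhantomConfig,
    expected_counts_from_truth,
    generate_phantom,
)
from iftomo.quantify import (
    CellCountReport,
    IntensityBins,
    classify_bin,
    count_subpopulations,
    min_volume_for_radius,
    multi_threshold_count,
    segment_nuclei,
)
from iftomo.volume import Volume, assemble


def _brute_force_bin(value):
    """Independent enumeration oracle for the default 8-bit grading."""
    if value < 100:
        return "low"
    if value < 200:
        return "mid"
    return "high"


class TestClassifyBin:
    @pytest.mark.parametrize(
        "value,expected",
        [(50, "low"), (150, "mid"), (220, "high"), (100, "mid"), (200, "high"),
         (0, "low"), (255, "high")],
    )
    def test_examples(self, value, expected):
        assert classify_bin(value) == expected

    def test_full_enumeration_matches_oracle(self):
        for v in range(256):
            assert classify_bin(v) == _brute_force_bin(v)

    @pytest.mark.parametrize("value", [-1, 256])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(ValueError):
            classify_bin(value)

    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            IntensityBins((0, 200, 100, 255))


class TestSegmentation:
    @pytest.fixture(scope="class")
    def phantom_volume(self):
        cfg = PhantomConfig(
            tissue_extent=(60, 60, 24), n_cells=15, nucleus_radius_range=(2.5, 3.5),
            divisions_max=8, noise_sd=0.0, seed=31,
        )
        sections, truth = generate_phantom(cfg)
        return assemble(sections), truth

    def test_single_sphere_found_with_centroid(self):
        cfg = PhantomConfig(
            tissue_extent=(30, 30, 16), n_cells=1, nucleus_radius_range=(3.0, 3.0),
            noise_sd=0.0, seed=8,
        )
        sections, truth = generate_phantom(cfg)
        vol = assemble(sections)
        objs = segment_nuclei(vol, "DAPI", threshold=250, min_volume_voxels=5)
        assert objs.n_objects == 1
        got = objs.objects.iloc[0]
        cx, cy, cz = truth.cells[0].centroid_um
        assert abs(got.centroid_x_um - cx) <= 0.44
        assert abs(got.centroid_y_um - cy) <= 0.44
        assert abs(got.centroid_z_um - cz) <= 2.0

    def test_all_nontouching_nuclei_counted(self, phantom_volume):
        vol, truth = phantom_volume
        objs = segment_nuclei(vol, "DAPI", threshold=250, min_volume_voxels=5)
        assert objs.n_objects == len(truth.cells)

    def test_empty_volume_has_zero_objects(self):
        vol = Volume(
            data=np.zeros((2, 4, 10, 10), dtype=np.uint8),
            voxel_size=(0.44, 0.44, 2.0),
            channel_names=["DAPI", "GFP"],
        )
        assert segment_nuclei(vol, "DAPI").n_objects == 0
        assert segment_nuclei(vol, "DAPI", threshold=10).n_objects == 0

    def test_raising_threshold_never_adds_foreground(self, phantom_volume):
        vol, _ = phantom_volume
        voxels = [
            np.count_nonzero(segment_nuclei(vol, "DAPI", threshold=t).label_volume)
            for t in (30, 90, 150, 210)
        ]
        assert all(a >= b for a, b in zip(voxels, voxels[1:]))

    def test_min_volume_filter_removes_small_objects(self, phantom_volume):
        vol, truth = phantom_volume
        huge = min_volume_for_radius(10.0, vol.voxel_size)
        objs = segment_nuclei(vol, "DAPI", threshold=250, min_volume_voxels=huge)
        assert objs.n_objects == 0

    def test_otsu_strategy_segments_without_explicit_threshold(self, phantom_volume):
        vol, truth = phantom_volume
        objs = segment_nuclei(vol, "DAPI", threshold="otsu", min_volume_voxels=5)
        assert objs.n_objects == len(truth.cells)


class TestCounting:
    def test_worked_percentages_from_printed_counts(self):
        """Bin counts 20/31/40 of 91 LRCs give 22/34/44 percent."""
        rep = CellCountReport.from_counts(654, per_bin=(40, 31, 20))
        assert rep.lrc_total == 91
        assert rep.per_bin_pct == (44, 34, 22)

    def test_single_bin_degenerate_pattern(self):
        rep = CellCountReport.from_counts(10, per_bin=(7, 0, 0))
        assert rep.per_bin_pct == (100, 0, 0)

    def test_zero_lrc_flagged_not_divided(self):
        rep = CellCountReport.from_counts(5, per_bin=(0, 0, 0))
        assert rep.no_lrc_flag and rep.per_bin_pct == (0, 0, 0)

    def test_conservation_enforced(self):
        with pytest.raises(ValueError):
            CellCountReport(
                total_nuclei=5, lrc_total=4, per_bin=(1, 1, 1),
                per_bin_pct=(0, 0, 0), per_bin_frac=(0, 0, 0),
            )
        with pytest.raises(ValueError):
            CellCountReport.from_counts(2, per_bin=(1, 1, 1))

    def test_counts_match_truth_table_oracle(self):
        """Measured counts equal brute-force computation on the truth table."""
        cfg = PhantomConfig(
            tissue_extent=(90, 90, 40), n_cells=60, nucleus_radius_range=(2.5, 3.5),
            divisions_max=8, noise_sd=0.0, seed=29,
        )
        sections, truth = generate_phantom(cfg)
        vol = assemble(sections)
        objs = segment_nuclei(vol, "DAPI", threshold=250, min_volume_voxels=5)
        rep = count_subpopulations(objs, "GFP", lrc_floor=1.0)
        expected = expected_counts_from_truth(truth)
        assert rep.total_nuclei == expected["total_nuclei"]
        assert rep.lrc_total == expected["lrc_total"]
        assert rep.per_bin == expected["per_bin"]
        assert sum(rep.per_bin) == rep.lrc_total <= rep.total_nuclei

    def test_percentages_sum_near_hundred(self):
        rep = CellCountReport.from_counts(654, per_bin=(40, 31, 20))
        assert abs(sum(rep.per_bin_pct) - 100) <= 1
        assert sum(rep.per_bin_frac) == pytest.approx(1.0)


class TestMultiThreshold:
    @pytest.fixture(scope="class")
    def vol(self):
        cfg = PhantomConfig(
            tissue_extent=(60, 60, 24), n_cells=15, nucleus_radius_range=(2.5, 3.5),
            noise_sd=0.0, seed=31,
        )
        sections, truth = generate_phantom(cfg)
        return assemble(sections), truth

    def test_mean_of_three_counts(self, vol):
        volume, truth = vol
        mean, counts = multi_threshold_count(
            volume, "DAPI", thresholds=(40, 80, 120), min_volume_voxels=5
        )
        assert mean == pytest.approx(np.mean(counts))
        assert counts == (len(truth.cells),) * 3
        assert mean == len(truth.cells)

    def test_identical_thresholds_reduce_to_single_count(self, vol):
        volume, _ = vol
        mean, counts = multi_threshold_count(
            volume, "DAPI", thresholds=(80, 80, 80), min_volume_voxels=5
        )
        assert counts[0] == counts[1] == counts[2]
        assert mean == counts[0]

    def test_decreasing_thresholds_rejected(self, vol):
        volume, _ = vol
        with pytest.raises(ValueError):
            multi_threshold_count(volume, "DAPI", thresholds=(120, 80, 40))
        with pytest.raises(ValueError):
            multi_threshold_count(volume, "DAPI", thresholds=(40, 80))
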