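"""Nucleus segmentation, label-retention binning and 3-D object counting.

Segmentation assigns labels to voxels by intensity thresholding (fixed
value or Otsu) followed by 3-D connected components (26-connectivity);
small specks below a minimum voxel volume are removed deterministically.
Label-retaining cells (LRCs) are objects with GFP signal, graded on the
8-bit range into three bins: low [0, 100), mid [100, 200) and high
[200, 255] — "200+" places 200 itself in the high bin, and the same
half-open convention is applied downward. Counting averages object counts
over three thresholds (high, medium, low) for a more robust mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import Volume

BIN_NAMES = ("low", "mid", "high")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class IntensityBins:
    """Ordered intensity edges grading label retention on the 8-bit range.

    Default (0, 100, 200, 255): low [0, 100), mid [100, 200), high
    [200, 255]. Interior edges belong to the bin above them; the last bin
    is closed at full scale.
    """

    edges: tuple[float, ...] = (0.0, 100.0, 200.0, 255.0)

    def __post_init__(self):
        e = self.edges
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError(f"bin edges must be strictly increasing, got {e}")
        if e[0] < 0:
            raise ValueError("first bin edge must be >= 0")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def classify(self, value: float) -> int:
        """Bin index for an intensity; raises outside [first, last] edge."""
        if not self.edges[0] <= value <= self.edges[-1]:
            raise ValueError(
                f"intensity {value} outside bin range "
                f"[{self.edges[0]}, {self.edges[-1]}]"
            )
        idx = int(np.searchsorted(self.edges[1:-1], value, side="right"))
        return idx


def classify_bin(mean_intensity: float, bins: IntensityBins | None = None) -> str:
    """Bin name ('low'/'mid'/'high' for the default 3-bin grading)."""
    bins = bins or IntensityBins()
    idx = bins.classify(mean_intensity)
    if bins.n_bins == 3:
        return BIN_NAMES[idx]
    return f"bin{idx}"


@dataclass
class LabeledObjects:
    """Segmented 3-D objects: a label raster plus a per-object table.

    ``objects`` columns: id, voxel_count, centroid_x/y/z_um (voxel units
    if the voxel size is unknown), and mean_<channel> for every channel.
    Labels are contiguous from 1 and match the ``id`` column.
    """

    label_volume: np.ndarray
    objects: pd.DataFrame
    channel_names: list[str] = field(default_factory=list)
    threshold_used: float | None = None

    @property
    def n_objects(self) -> int:
        return len(self.objects)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def min_volume_for_radius(radius_um: float, voxel_size) -> int:
    """Voxel count of a sphere of the given radius at the volume's voxel size."""
    vx, vy, vz = voxel_size
    sphere = 4.0 / 3.0 * math.pi * radius_um**3
    return max(int(sphere / (vx * vy * vz)), 1)


def _resolve_threshold(channel_data: np.ndarray, threshold) -> float:
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold strategy {threshold!r}")
        if channel_data.min() == channel_data.max():
            # flat channel: no objects at any threshold
            return float(channel_data.max())
        return float(threshold_otsu(channel_data))
    return float(threshold)


def segment_nuclei(
    volume: Volume,
    channel: str = "DAPI",
    threshold="otsu",
    min_volume_voxels: int = 0,
) -> LabeledObjects:
    """Threshold a channel and label 3-D connected components.

    Voxels strictly above the threshold (fixed value, or Otsu on the
    channel histogram when ``threshold="otsu"``) are foreground; components
    use 26-connectivity and those below ``min_volume_voxels`` are removed.
    Per-object voxel count, centroid (µm when the voxel size is known) and
    mean intensity in every channel are tabulated. An all-zero channel
    yields zero objects, not an error.
    """
    ch = np.asarray(volume.channel(channel), dtype=float)
    thr = _resolve_threshold(ch, threshold)
    mask = ch > thr
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n and min_volume_voxels > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_volume_voxels)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    # relabel contiguously from 1
    labels, n = ndimage.label(labels > 0, structure=_STRUCT_26)

    rows = []
    if n:
        ids = np.arange(1, n + 1)
        counts = ndimage.sum_labels(np.ones_like(labels), labels, ids)
        centroids = ndimage.center_of_mass(mask, labels, ids)  # (z, y, x) voxel
        vx, vy, vz = volume.voxel_size if volume.voxel_size else (1.0, 1.0, 1.0)
        means = {
            name: ndimage.mean(volume.data[k].astype(float), labels, ids)
            for k, name in enumerate(volume.channel_names)
        }
        for i, obj_id in enumerate(ids):
            cz, cy, cx = centroids[i]
            row = {
                "id": int(obj_id),
                "voxel_count": int(counts[i]),
                "centroid_x_um": cx * vx,
                "centroid_y_um": cy * vy,
                "centroid_z_um": (cz + 0.5) * vz,  # slab centers, not slab starts
            }
            for name in volume.channel_names:
                row[f"mean_{name}"] = float(means[name][i])
            rows.append(row)
    columns = ["id", "voxel_count", "centroid_x_um", "centroid_y_um", "centroid_z_um"]
    columns += [f"mean_{n}" for n in volume.channel_names]
    objects = pd.DataFrame(rows, columns=columns)
    return LabeledObjects(
        label_volume=labels,
        objects=objects,
        channel_names=list(volume.channel_names),
        threshold_used=thr,
    )


@dataclass
class CellCountReport:
    """Sub-population counts for one quantified volume.

    per_bin / per_bin_pct are ordered (low, mid, high); percentages are of
    the LRC total, rounded to the nearest integer (raw fractions kept in
    per_bin_frac). Conservation (bins sum to lrc_total <= total_nuclei) is
    asserted at construction.
    """

    total_nuclei: int
    lrc_total: int
    per_bin: tuple[int, ...]
    per_bin_pct: tuple[int, ...]
    per_bin_frac: tuple[float, ...]
    thresholds_used: list = field(default_factory=list)
    lrc_floor: float | None = None
    bin_edges: tuple | None = None
    no_lrc_flag: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if sum(self.per_bin) != self.lrc_total:
            raise ValueError("per-bin counts must sum to lrc_total")
        if self.lrc_total > self.total_nuclei:
            raise ValueError("lrc_total cannot exceed total_nuclei")

    @classmethod
    def from_counts(
        cls,
        total_nuclei: int,
        per_bin: tuple[int, ...],
        **kwargs,
    ) -> "CellCountReport":
        """Build a report from raw bin counts (low, mid, high)."""
        lrc_total = int(sum(per_bin))
        if lrc_total > 0:
            frac = tuple(c / lrc_total for c in per_bin)
            pct = tuple(_round_half_up(f * 100.0) for f in frac)
            flag = False
        else:
            frac = tuple(0.0 for _ in per_bin)
            pct = tuple(0 for _ in per_bin)
            flag = True
        return cls(
            total_nuclei=int(total_nuclei),
            lrc_total=lrc_total,
            per_bin=tuple(int(c) for c in per_bin),
            per_bin_pct=pct,
            per_bin_frac=frac,
            no_lrc_flag=flag,
            **kwargs,
        )

    def as_dict(self) -> dict:
        return {
            "total_nuclei": self.total_nuclei,
            "lrc_total": self.lrc_total,
            "per_bin": {n: c for n, c in zip(BIN_NAMES, self.per_bin)},
            "per_bin_pct": {n: p for n, p in zip(BIN_NAMES, self.per_bin_pct)},
            "per_bin_frac": {n: f for n, f in zip(BIN_NAMES, self.per_bin_frac)},
            "thresholds_used": self.thresholds_used,
            "lrc_floor": self.lrc_floor,
            "bin_edges": list(self.bin_edges) if self.bin_edges else None,
            "no_lrc_flag": self.no_lrc_flag,
            "provenance": self.provenance,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def count_subpopulations(
    objects: LabeledObjects,
    lrc_channel: str = "GFP",
    lrc_floor: float = 1.0,
    bins: IntensityBins | None = None,
) -> CellCountReport:
    """Count nuclei and grade label-retaining sub-populations.

    Every segmented object is a nucleus; objects whose mean intensity in
    the label channel reaches ``lrc_floor`` count as LRCs and are graded
    by :func:`classify_bin` on that mean. With zero LRCs, percentages are
    reported as 0 with a flag rather than dividing by zero.
    """
    bins = bins or IntensityBins()
    col = f"mean_{lrc_channel}"
    if col not in objects.objects.columns:
        raise KeyError(f"no channel {lrc_channel!r} in object table")
    means = objects.objects[col].to_numpy()
    lrc_means = means[means >= lrc_floor]
    counts = [0] * bins.n_bins
    for m in lrc_means:
        counts[bins.classify(min(float(m), bins.edges[-1]))] += 1
    return CellCountReport.from_counts(
        total_nuclei=objects.n_objects,
        per_bin=tuple(counts),
        thresholds_used=[objects.threshold_used],
        lrc_floor=lrc_floor,
        bin_edges=bins.edges,
    )


def multi_threshold_count(
    volume: Volume,
    channel: str = "DAPI",
    thresholds: tuple[float, float, float] = (50.0, 100.0, 150.0),
    min_volume_voxels: int = 0,
) -> tuple[float, tuple[int, int, int]]:
    """3-D object count averaged over three signal thresholds.

    Segments at each of the (low, medium, high) thresholds and returns the
    arithmetic mean of the three object counts together with the triple.
    Thresholds must be non-decreasing (equal thresholds reduce to a single
    count).
    """
    if len(thresholds) != 3:
        raise ValueError("exactly 3 thresholds required")
    if not (thresholds[0] <= thresholds[1] <= thresholds[2]):
        raise ValueError(f"thresholds must be non-decreasing, got {thresholds}")
    counts = tuple(
        segment_nuclei(
            volume, channel=channel, threshold=t, min_volume_voxels=min_volume_voxels
        ).n_objects
        for t in thresholds
    )
    return float(np.mean(counts)), counts
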