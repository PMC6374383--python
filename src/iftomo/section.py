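"""Section images: one physical serial section as a multi-channel raster.

Sections are stored on disk as one multi-page TIFF per section (one page
per channel, DAPI first by convention) with acquisition metadata embedded
as JSON in the TIFF description, plus a ``manifest.json`` listing the
ordered sections of a dataset together with pixel size and thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

MANIFEST_NAME = "manifest.json"
SECTION_PATTERN = "section_%04d.tif"


@dataclass
class SectionImage:
    """Multi-channel 2-D raster of one serial section plus metadata.

    data
        Array of shape (channels, rows, cols); 8- or 16-bit unsigned.
    channel_names
        One name per channel, e.g. ``["DAPI", "GFP"]``.
    index
        Position of the section in the cutting order (0-based).
    pixel_size
        Lateral pixel pitch in micrometres (x and y).
    thickness
        Physical section thickness in micrometres (the axial resolution).
    """

    data: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    index: int = 0
    pixel_size: float | None = None
    thickness: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"section data must be (C, Y, X), got {self.data.shape}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of one channel plane."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """2-D view of the named channel."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[i]

    def with_data(self, data: np.ndarray, channel_names=None) -> "SectionImage":
        return replace(
            self,
            data=data,
            channel_names=list(channel_names or self.channel_names),
        )


def write_section(section: SectionImage, path) -> None:
    meta = {
        "channel_names": section.channel_names,
        "index": section.index,
        "pixel_size_um": section.pixel_size,
        "thickness_um": section.thickness,
    }
    tifffile.imwrite(
        path,
        section.data,
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_section(path) -> SectionImage:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return SectionImage(
        data=data,
        channel_names=list(meta.get("channel_names", [])),
        index=int(meta.get("index", 0)),
        pixel_size=meta.get("pixel_size_um"),
        thickness=meta.get("thickness_um"),
    )


def write_sections(sections: list[SectionImage], outdir) -> Path:
    """Write an ordered section series plus its manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, sec in enumerate(sections):
        name = SECTION_PATTERN % i
        write_section(sec, outdir / name)
        names.append(name)
    first = sections[0] if sections else None
    manifest = {
        "sections": names,
        "n_sections": len(names),
        "channel_names": first.channel_names if first else [],
        "pixel_size_um": first.pixel_size if first else None,
        "thickness_um": first.thickness if first else None,
    }
    manifest_path = outdir / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_sections(manifest_path) -> list[SectionImage]:
    """Read the ordered section series described by a manifest.json."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    sections = []
    for i, name in enumerate(manifest["sections"]):
        sec = read_section(root / name)
        sec.index = i
        if sec.pixel_size is None:
            sec.pixel_size = manifest.get("pixel_size_um")
        if sec.thickness is None:
            sec.thickness = manifest.get("thickness_um")
        sections.append(sec)
    return sections
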