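"""Anisotropic-voxel 3-D volume assembly and I/O.

Aligned sections are stacked along z into a (channel, z, y, x) raster.
The lateral voxel size is the pixel pitch of the 2-D images (0.44 µm with
the 20X objective used as reference); the axial voxel size is the physical
section thickness (2 µm), so the z extent in micrometres is always the
number of sections times the thickness. No resampling to isotropic voxels
happens here — the axial resolution *is* the section thickness and is
preserved.

Storage is one multi-page TIFF per channel (one page per z slice) plus a
``volume.json`` sidecar holding voxel size, channel names and provenance;
round-trips are bit-exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .section import SectionImage

SIDECAR_NAME = "volume.json"


@dataclass
class Volume:
    """Aligned multi-channel 3-D raster with anisotropic voxel size.

    data
        Array of shape (channel, z, y, x) — this axis order is fixed in
        all contracts.
    voxel_size
        (x, y, z) in micrometres; z equals the section thickness.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] | None
    channel_names: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"volume data must be (C, Z, Y, X), got {self.data.shape}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_sections(self) -> int:
        return self.data.shape[1]

    @property
    def z_extent_um(self) -> float | None:
        """Reconstructed depth in micrometres: n_sections x thickness."""
        if self.voxel_size is None:
            return None
        return self.n_sections * self.voxel_size[2]

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None
        return self.data[i]


def assemble(
    sections: list[SectionImage],
    thickness: float | None = None,
    pixel_size: float | None = None,
) -> Volume:
    """Stack aligned sections in order along z into a Volume.

    Thickness and pixel size default to the section metadata. The z extent
    invariant (n_sections x thickness) is asserted on every assembly.
    """
    if not sections:
        raise ValueError("cannot assemble an empty section list")
    first = sections[0]
    for i, s in enumerate(sections):
        if s.shape != first.shape or s.n_channels != first.n_channels:
            raise ValueError(
                f"section {i} shape {s.data.shape} differs from section 0 "
                f"{first.data.shape}"
            )
    thickness = thickness if thickness is not None else first.thickness
    pixel_size = pixel_size if pixel_size is not None else first.pixel_size
    data = np.stack([s.data for s in sections], axis=1)  # (C, Z, Y, X)
    voxel = None
    if thickness is not None and pixel_size is not None:
        voxel = (float(pixel_size), float(pixel_size), float(thickness))
    vol = Volume(
        data=data,
        voxel_size=voxel,
        channel_names=list(first.channel_names),
        provenance={"n_sections": len(sections)},
    )
    if voxel is not None:
        assert abs(vol.z_extent_um - len(sections) * thickness) < 1e-9
    return vol


def write_stack(volume: Volume, outdir) -> Path:
    """One multi-page TIFF per channel + volume.json sidecar; returns sidecar path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, planes in zip(volume.channel_names, volume.data):
        fname = f"{name}.tif"
        tifffile.imwrite(outdir / fname, planes, photometric="minisblack")
        files[name] = fname
    sidecar = {
        "channel_names": volume.channel_names,
        "channel_files": files,
        "voxel_size_um": list(volume.voxel_size) if volume.voxel_size else None,
        "n_sections": volume.n_sections,
        "provenance": volume.provenance,
    }
    path = outdir / SIDECAR_NAME
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path) -> Volume:
    """Read a volume written by :func:`write_stack`.

    A missing sidecar is tolerated with a warning: channel TIFFs are
    discovered by glob and the voxel size is marked unknown (None). An
    empty or non-existent directory is an error.
    """
    path = Path(path)
    sidecar = path / SIDECAR_NAME if path.is_dir() else path
    if sidecar.name != SIDECAR_NAME and sidecar.is_dir():
        sidecar = sidecar / SIDECAR_NAME
    root = sidecar.parent
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names = meta["channel_names"]
        files = meta.get("channel_files", {n: f"{n}.tif" for n in names})
        data = np.stack([tifffile.imread(root / files[n]) for n in names])
        voxel = tuple(meta["voxel_size_um"]) if meta.get("voxel_size_um") else None
        return Volume(
            data=data,
            voxel_size=voxel,
            channel_names=list(names),
            provenance=meta.get("provenance", {}),
        )
    if not root.is_dir():
        raise FileNotFoundError(f"no such volume directory: {root}")
    tifs = sorted(root.glob("*.tif"))
    if not tifs:
        raise FileNotFoundError(f"no volume data found in {root}")
    warnings.warn(
        f"{SIDECAR_NAME} missing in {root}; voxel size unknown", stacklevel=2
    )
    data = np.stack([tifffile.imread(f) for f in tifs])
    return Volume(
        data=data,
        voxel_size=None,
        channel_names=[f.stem for f in tifs],
    )


def slide_capacity(
    ribbons: int = 3,
    sections_per_ribbon: int = 25,
    thickness: float = 2.0,
) -> float:
    """Tissue depth (µm) reconstructable from one slide of section ribbons.

    With up to 3 ribbons of 25 serial sections cut at 2 µm, one slide
    carries 150 µm of tissue.
    """
    if ribbons < 1 or sections_per_ribbon < 1 or thickness <= 0:
        raise ValueError("ribbons, sections_per_ribbon and thickness must be positive")
    return ribbons * sections_per_ribbon * thickness
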