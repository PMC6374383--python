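"""End-to-end pipeline orchestration: simulate -> stitch -> align -> assemble -> quantify.

Each stage is usable on its own through the library (or the CLI
subcommands); :func:`run_pipeline` chains the enabled stages, writes every
artifact under the configured output directory and records the resolved
configuration, seed and per-stage timings in ``run.json`` so any run is
reproducible from that record alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import phantom as ph
from . import mosaic as mo
from .config import PipelineConfig, save_run_record
from .quantify import IntensityBins, count_subpopulations, min_volume_for_radius, segment_nuclei
from .register import align_stack
from .section import SectionImage, read_sections, write_sections
from .volume import assemble, write_stack

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns a dict of artifact paths/results."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    timings: dict[str, float] = {}
    artifacts: dict = {"outdir": str(outdir)}
    sections: list[SectionImage] | None = None
    truth = None

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", stage)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[stage] = round(time.perf_counter() - self.t0, 3)
                log.info("stage %s: %.2fs", stage, timings[stage])
                return False

        return _T()

    stages = config.stages
    try:
        if "simulate" in stages:
            with timed("simulate"):
                pcfg = config.phantom
                pcfg.seed = config.seed
                sections, truth = ph.generate_phantom(pcfg)
                secdir = outdir / "sections"
                tile_rng = np.random.default_rng(config.seed + 1)
                if pcfg.tile_grid is not None:
                    tiledir = outdir / "tiles"
                    tiledir.mkdir(parents=True, exist_ok=True)
                    tile_offsets = []
                    tiled_sections = []
                    import tifffile

                    for sec in sections:
                        tiles, nominal, true = ph.tile_section(
                            sec,
                            pcfg.tile_grid,
                            pcfg.tile_overlap_fraction,
                            jitter_px=pcfg.tile_jitter_px,
                            rng=tile_rng,
                        )
                        for k, tile in enumerate(tiles):
                            tifffile.imwrite(
                                tiledir / f"sec_{sec.index:04d}_tile_{k:03d}.tif",
                                tile,
                                photometric="minisblack",
                            )
                        tile_offsets.append([list(o) for o in true])
                        tiled_sections.append((tiles, nominal))
                    truth.tile_offsets = tile_offsets
                    artifacts["tiles"] = tiled_sections
                manifest = write_sections(sections, secdir)
                truth.save(outdir / ph.TRUTH_NAME)
                artifacts["manifest"] = str(manifest)
                artifacts["truth"] = str(outdir / ph.TRUTH_NAME)
        elif {"stitch", "align", "assemble", "quantify"} & set(stages):
            sections = read_sections(Path(config.outdir) / "sections")

        if "stitch" in stages and config.phantom.tile_grid is not None:
            with timed("stitch"):
                stitched = []
                for i, (tiles, _nominal) in enumerate(artifacts.get("tiles", [])):
                    sec, _layout = mo.stitch_mosaic(
                        tiles,
                        config.phantom.tile_grid,
                        config.phantom.tile_overlap_fraction,
                        blend=config.stitch.blend,
                        refine=config.stitch.refine,
                        search_radius=config.stitch.search_radius,
                        pixel_size=sections[i].pixel_size,
                        thickness=sections[i].thickness,
                        channel_names=sections[i].channel_names,
                        index=i,
                    )
                    stitched.append(sec)
                write_sections(stitched, outdir / "stitched")
                sections = stitched
                artifacts["stitched"] = str(outdir / "stitched")

        aligned = sections
        if "align" in stages:
            with timed("align"):
                r = config.register
                result, aligned = align_stack(
                    sections,
                    channel=r.channel,
                    reference_index=r.reference_index,
                    max_rotation=r.max_rotation,
                    max_translation=r.max_translation,
                    angle_step=r.angle_step,
                    confidence_floor=r.confidence_floor,
                )
                write_sections(aligned, outdir / "aligned")
                (outdir / "transforms.json").write_text(
                    json.dumps(result.as_dict(), indent=2)
                )
                artifacts["alignment"] = result
                artifacts["transforms"] = str(outdir / "transforms.json")

        vol = None
        if "assemble" in stages:
            with timed("assemble"):
                vol = assemble(aligned)
                write_stack(vol, outdir / "volume")
                artifacts["volume"] = str(outdir / "volume")

        if "quantify" in stages:
            with timed("quantify"):
                q = config.quantify
                min_vol = q.min_volume_voxels
                if min_vol is None:
                    min_vol = min_volume_for_radius(
                        config.phantom.nucleus_radius_range[0],
                        vol.voxel_size or (1.0, 1.0, 1.0),
                    )
                objects = segment_nuclei(
                    vol,
                    channel=q.channel,
                    threshold=q.threshold,
                    min_volume_voxels=min_vol,
                )
                report = count_subpopulations(
                    objects,
                    lrc_channel=q.lrc_channel,
                    lrc_floor=q.lrc_floor,
                    bins=IntensityBins(tuple(q.bin_edges)),
                )
                objects.objects.to_csv(outdir / "objects.csv", index=False)
                report.save(outdir / "report.json")
                artifacts["objects"] = str(outdir / "objects.csv")
                artifacts["report"] = report
    except Exception as exc:  # noqa: BLE001 - stage-named abort contract
        stage = timings and list(timings)[-1] or "setup"
        raise StageError(stage, exc) from exc

    save_run_record(config, outdir / "run.json", timings)
    artifacts["run_record"] = str(outdir / "run.json")
    artifacts["timings"] = timings
    if truth is not None:
        artifacts["truth_obj"] = truth
    return artifacts
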