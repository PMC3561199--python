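"""End-to-end pipeline: simulate -> tile/stitch -> segment -> quantify ->
regions -> paired comparison, emitting one machine-readable report.

The pipeline exists to exercise every stage against ground truth at desk
scale: each synthetic specimen contributes a PP-rich and a PP-poor section
(optionally a rich-only specimen, which the pairing then excludes), and one
specimen additionally contributes a head-to-tail block series for boundary
detection. All randomness derives from a single integer seed, so reports
are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field, asdict

from . import __version__
from .morphometry import detect_objects, objects_to_frame
from .regional import classify_regions, summarize_section, summaries_to_frame
from .segmentation import SegmentationParams, area_fractions, segment_channels
from .stats import SpecimenRegions, compare_regions
from .synthetic import (
    GeneratorConfig,
    generate_block_series,
    generate_section,
    pp_poor_config,
    pp_rich_config,
    render_tiles,
    series_configs,
)
from .vslice import stitch


class PipelineError(RuntimeError):
    """A stage failure, tagged with the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    n_specimens: int = 3
    include_rich_only_specimen: bool = False
    image_size: tuple[int, int] = (512, 512)
    series_blocks: int = 8
    series_boundary: int = 3
    series_image_size: tuple[int, int] = (256, 256)
    tile_size: int = 192
    tile_overlap: int = 16
    merge_radius: float = 10.0
    pp_rich_threshold: float = 0.2
    alpha: float = 0.05

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _specimen_seed(base: int, specimen: int, region_flag: int) -> int:
    return (base * 1_000_003 + specimen * 7919 + region_flag * 104_729 + 17) % (2**31)


def _measure_section(cfg: GeneratorConfig, pipe: PipelineConfig, section_id: str):
    """simulate -> tile -> stitch -> segment -> contour -> summarize."""
    stack, truth = generate_section(cfg, section_id=section_id)
    grid = render_tiles(stack, pipe.tile_size, pipe.tile_overlap)
    restitched = stitch(grid)  # exercises the montage path end to end
    masks = segment_channels(restitched, SegmentationParams())
    fractions, meta = area_fractions(masks, denominator="tissue")
    objects = detect_objects(masks, merge_radius=pipe.merge_radius)
    summary = summarize_section(objects, fractions, section_id=section_id)
    return stack, truth, masks, fractions, objects, summary


def run_pipeline(
    config: PipelineConfig | None = None, out_dir: str | pathlib.Path | None = None
) -> dict:
    """Run the full synthetic study and return the report dict.

    When ``out_dir`` is given, writes ``report.json`` plus per-stage CSVs
    (per-object morphometry and per-block summaries).
    """
    cfg = config or PipelineConfig()
    report: dict = {
        "provenance": {
            "package": "isletquant",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.content_hash(),
            "config": asdict(cfg),
        }
    }

    specimens = []
    specimen_rows = []
    object_frames = []
    try:
        for i in range(cfg.n_specimens):
            sid = f"S{i + 1}"
            rich_only = cfg.include_rich_only_specimen and i == cfg.n_specimens - 1
            rich_cfg = pp_rich_config(image_size=cfg.image_size)
            rich_cfg.seed = _specimen_seed(cfg.seed, i, 0)
            _, _, _, rich_fracs, rich_objs, _ = _measure_section(
                rich_cfg, cfg, f"{sid}_rich"
            )
            object_frames.append(objects_to_frame(rich_objs).assign(section=f"{sid}_rich"))
            if rich_only:
                specimens.append(SpecimenRegions(sid, rich=rich_fracs, poor=None))
                specimen_rows.append({"specimen": sid, "region": "pp_rich", **rich_fracs})
                continue
            poor_cfg = pp_poor_config(image_size=cfg.image_size)
            poor_cfg.seed = _specimen_seed(cfg.seed, i, 1)
            _, _, _, poor_fracs, poor_objs, _ = _measure_section(
                poor_cfg, cfg, f"{sid}_poor"
            )
            object_frames.append(objects_to_frame(poor_objs).assign(section=f"{sid}_poor"))
            specimens.append(SpecimenRegions(sid, rich=rich_fracs, poor=poor_fracs))
            specimen_rows.append({"specimen": sid, "region": "pp_rich", **rich_fracs})
            specimen_rows.append({"specimen": sid, "region": "pp_poor", **poor_fracs})
    except Exception as e:  # noqa: BLE001
        raise PipelineError("sections", e) from e

    try:
        comparisons, exclusions = compare_regions(specimens, alpha=cfg.alpha)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("compare", e) from e
    report["specimens"] = specimen_rows
    report["comparisons"] = [c.to_dict() for c in comparisons]
    report["exclusions"] = exclusions

    try:
        s_cfgs = series_configs(
            cfg.series_blocks,
            cfg.series_boundary,
            seed=_specimen_seed(cfg.seed, 99, 2),
            image_size=cfg.series_image_size,
        )
        series = generate_block_series(s_cfgs)
        summaries = []
        for idx, (stack, _truth) in enumerate(series):
            masks = segment_channels(stack)
            fracs, _ = area_fractions(masks)
            objs = detect_objects(masks, merge_radius=cfg.merge_radius)
            summaries.append(
                summarize_section(objs, fracs, section_id=f"block{idx:02d}", block_index=idx)
            )
        region_series = classify_regions(summaries, threshold=cfg.pp_rich_threshold)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("series", e) from e
    report["series"] = {
        "pp_fractions_percent": [s.pp_fraction for s in summaries],
        "region_labels": region_series.region_labels,
        "boundary_index": region_series.boundary_index,
        "threshold_percent": cfg.pp_rich_threshold,
    }

    if out_dir is not None:
        import pandas as pd

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        if object_frames:
            pd.concat(object_frames, ignore_index=True).to_csv(
                out / "islets.csv", index=False
            )
        summaries_to_frame(summaries).to_csv(out / "blocks.csv", index=False)
    return report
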