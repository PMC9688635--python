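"""End-to-end pipeline: images in, classified objects and counts out.

Each run estimates the background, segments dark objects, computes per-band
deficits and class labels, summarizes the stained classes, and — given a
first/last compartment pair — the transport efficiency.  Reports embed the
config and its hash, so a result is reproducible from its own output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import imageio.v3 as iio
import numpy as np

from . import __version__
from .color import (
    ClassificationRule,
    band_differences,
    classify_object,
    summarize_differences,
)
from .config import PipelineConfig
from .errors import ConfigurationError, ImageFormatError, SampleSizeError
from .quantify import estimate_count, mean_cell_area, transport_efficiency
from .segmentation import (
    default_min_object_area,
    estimate_background,
    objects_to_frame,
    segment_objects,
)
from .synthetic import DEFAULT_OPTICS, SceneSpec, make_compartment_pair, render_scene

log = logging.getLogger("stainsight")


def read_image(path: str | Path, auto_convert: bool = True) -> np.ndarray:
    """Read an 8-bit RGB raster (PNG/TIFF).

    Grayscale input is replicated to three bands and RGBA alpha dropped when
    ``auto_convert`` is on; 16-bit or other exotic inputs are rejected.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # plugin backends raise a zoo of error types
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ImageFormatError(
            f"{path}: expected 8-bit input, got dtype {arr.dtype}"
        )
    if arr.ndim == 2:
        if not auto_convert:
            raise ImageFormatError(f"{path}: grayscale input (auto-convert off)")
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        if not auto_convert:
            raise ImageFormatError(f"{path}: RGBA input (auto-convert off)")
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"{path}: not an RGB image (shape {arr.shape})")
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), image)


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    """Write a report as UTF-8 JSON with stable key ordering."""
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n",
        encoding="utf-8",
    )


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def _analyze_image(
    image: np.ndarray, config: PipelineConfig, rule: ClassificationRule,
    compartment: str,
) -> dict[str, Any]:
    bg = estimate_background(image)
    min_area = (
        config.min_object_area
        if config.min_object_area is not None
        else default_min_object_area(config.optics.pixel_scale)
    )
    objects = segment_objects(
        image, bg, min_deficit=config.min_deficit, min_object_area=min_area
    )
    log.info("%s: %d objects segmented", compartment, len(objects))
    diffs = [band_differences(o, bg) for o in objects]
    labels = [classify_object(d, rule) for d in diffs]
    table = objects_to_frame(objects)
    table["class"] = labels
    try:
        summary = summarize_differences(list(zip(labels, diffs)), allow_fewer=False)
        summary_dict = {
            "per_class": summary.table.to_dict(orient="index"),
            "overall_min": summary.overall_min,
            "overall_max": summary.overall_max,
        }
    except SampleSizeError as exc:
        summary_dict = {"warning": str(exc)}
    try:
        cell_area = mean_cell_area(
            objects, cluster_cutoff_factor=config.cluster_cutoff_factor
        )
        report = estimate_count(
            objects,
            cell_area,
            compartment=compartment,
            ultra_low_max=config.ultra_low_max,
            pixel_scale=config.optics.pixel_scale,
        )
        quant = report.to_dict()
    except SampleSizeError as exc:
        report = None
        quant = {"warning": str(exc)}
    return {
        "background": {"mean_rgb": list(bg.mean_rgb), "sd_rgb": list(bg.sd_rgb)},
        "n_objects": len(objects),
        "objects": table.to_dict(orient="records"),
        "summary": summary_dict,
        "quantification": quant,
        "_report": report,
    }


def run_pipeline(
    config: PipelineConfig,
    first: str | Path | np.ndarray | None = None,
    last: str | Path | np.ndarray | None = None,
    simulate: Mapping[str, Any] | None = None,
) -> dict[str, Any]:
    """Run background -> segmentation -> classification -> quantification.

    Provide either first (and optionally last) compartment images, or a
    ``simulate`` directive, e.g. ``{"density": "ultra_low",
    "loss_fraction": 0.19}``, which renders a matched compartment pair with
    the config's seed and optics.
    """
    if simulate is None and first is None:
        raise ConfigurationError("provide images or a simulate directive")
    rule = ClassificationRule.from_profiles(
        config.stain_profiles(), stage1_min_deficit=config.stage1_min_deficit
    )
    images: dict[str, np.ndarray] = {}
    if simulate is not None:
        density = simulate.get("density", "ultra_low")
        loss = float(simulate.get("loss_fraction", 0.0))
        stain = simulate.get("stain", "TB")
        spec_first, spec_last = make_compartment_pair(
            density, loss, seed=config.seed, stain=stain, optics=config.optics
        )
        images["first"], _ = render_scene(spec_first)
        images["last"], _ = render_scene(spec_last)
    else:
        images["first"] = first if isinstance(first, np.ndarray) else read_image(first)
        if last is not None:
            images["last"] = last if isinstance(last, np.ndarray) else read_image(last)

    report: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "version": __version__,
        "compartments": {},
    }
    stage_reports = {}
    for name, image in images.items():
        result = _analyze_image(image, config, rule, name)
        stage_reports[name] = result.pop("_report")
        report["compartments"][name] = result
    if "first" in stage_reports and "last" in stage_reports:
        rf, rl = stage_reports["first"], stage_reports["last"]
        if rf is not None and rl is not None:
            report["efficiency"] = transport_efficiency(rf, rl).to_dict()
    return report


def simulate_scene(
    config: PipelineConfig,
    counts: Mapping[str, int],
    placement: str = "non_overlapping",
) -> tuple[np.ndarray, dict]:
    """Render one scene under the config's optics and seed."""
    spec = SceneSpec(
        optics=config.optics,
        counts=dict(counts),
        placement=placement,
        stain_overrides=config.stain_profiles(),
        seed=config.seed,
    )
    image, gt = render_scene(spec)
    return image, gt.to_dict()
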