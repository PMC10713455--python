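"""End-to-end pipeline: simulate -> segment -> classify -> evaluate.

Chains the library modules under a single seeded configuration and
writes all artifacts (rasters, instance tables, overlays, JSON report)
with an embedded config hash, so identical config + seed reproduces an
identical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as eio
from .core import PixelScale, class_templates
from .instances import (FilterParams, classify_patch, extract_instances,
                        extract_masked_patch, filter_instances)
from .metrics import evaluate_dataset
from .segment import (MatchedFilterEngine, PostprocessParams, argmax_map,
                      postprocess, sliding_window_predict)
from .simulate import SceneSpec, coerce_scene_config, render_scene

__all__ = ["RunConfig", "StageError", "run_pipeline", "segment_image",
           "classify_instances"]

log = logging.getLogger("emcaps")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    n_scenes: int = 2
    scene: dict = field(default_factory=dict)
    pixel_size_nm: float = 1.81
    window_px: int = 512
    overlap: float = 0.5
    tta: bool = False
    argmax_mode: str = "six"
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    filters: FilterParams = field(default_factory=FilterParams)
    patch_px: int = 49
    save_probs: bool = False
    raw: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        return eio.config_hash({"seed": self.seed, "n_scenes": self.n_scenes,
                                "scene": {k: str(v) for k, v in self.scene.items()},
                                "pixel_size_nm": self.pixel_size_nm,
                                "argmax_mode": self.argmax_mode})


def segment_image(micrograph, engine=None, window_px=512, overlap=0.5,
                  tta=False, argmax_mode="six",
                  params: PostprocessParams | None = None, seed=0):
    """Predict, argmax and postprocess one micrograph; returns (labels, stack)."""
    scale = getattr(micrograph, "scale", None) or PixelScale()
    engine = engine or MatchedFilterEngine(class_templates(scale), scale)
    raster = micrograph.pixels if hasattr(micrograph, "pixels") else micrograph
    h, w = raster.shape
    window = min(window_px, h, w)
    stack = sliding_window_predict(engine, raster, window, overlap,
                                   tta=tta, seed=seed)
    labels = postprocess(argmax_map(stack, argmax_mode), params)
    return labels, stack


def classify_instances(raster, labels, templates, scale,
                       filters: FilterParams | None = None, patch_px: int = 49):
    """Extract, filter and radial-profile-classify instances of a label map."""
    records = extract_instances(labels)
    records = filter_instances(records, filters or FilterParams(), labels.shape)
    for rec in records:
        if rec.exclusion_reason.value != "none":
            continue
        patch = extract_masked_patch(raster, rec, patch_px)
        cls, scores = classify_patch(patch, templates, scale)
        rec.class_id = int(cls)
        rec.scores = scores
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> segment -> classify -> evaluate; return the report.

    Per-stage timings and object counts are logged; any stage failure is
    re-raised as :class:`StageError` naming the stage and input.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scale = PixelScale(config.pixel_size_nm)
    templates = class_templates(scale)
    engine = MatchedFilterEngine(templates, scale)
    report: dict = {"config_hash": config.hash, "seed": config.seed, "stages": {}}

    gt_maps, pred_maps = [], []
    for i in range(config.n_scenes):
        stage = f"simulate[{i}]"
        t0 = time.perf_counter()
        try:
            scene_cfg = coerce_scene_config(config.scene)
            scene_cfg.pop("scale", None)
            spec = SceneSpec(**scene_cfg, scale=scale, seed=config.seed + i)
            mic, gt = render_scene(spec, templates)
        except Exception as exc:
            raise StageError(f"{stage}: {exc}") from exc
        eio.write_image(mic, out / f"scene_{i:03d}.tif")
        eio.write_labels(gt.semantic, out / f"scene_{i:03d}_gt.png")
        log.info("%s: %d instances (%.2fs)", stage, len(gt.instances),
                 time.perf_counter() - t0)

        stage = f"segment[{i}]"
        t0 = time.perf_counter()
        try:
            labels, stack = segment_image(
                mic, engine, config.window_px, config.overlap, config.tta,
                config.argmax_mode, config.postprocess, config.seed)
        except Exception as exc:
            raise StageError(f"{stage}: scene_{i:03d}.tif: {exc}") from exc
        eio.write_labels(labels, out / f"scene_{i:03d}_pred.png")
        if config.save_probs:
            import tifffile
            tifffile.imwrite(out / f"scene_{i:03d}_probs.tif",
                             stack.astype(np.float32))
        _write_overlay(mic, labels, out / f"scene_{i:03d}_overlay.png")
        log.info("%s: %d fg px (%.2fs)", stage, int((labels > 0).sum()),
                 time.perf_counter() - t0)

        stage = f"classify[{i}]"
        try:
            records = classify_instances(mic.pixels, labels, templates, scale,
                                         config.filters, config.patch_px)
        except Exception as exc:
            raise StageError(f"{stage}: scene_{i:03d}.tif: {exc}") from exc
        frame = eio.records_to_frame(records)
        frame.to_csv(out / f"scene_{i:03d}_instances.csv", index=False)
        gt_maps.append(gt.semantic)
        pred_maps.append(labels)
        report["stages"][f"scene_{i:03d}"] = {
            "true_instances": len(gt.instances),
            "detected_instances": len(records),
            "classified": int((frame["exclusion_reason"] == "none").sum())
            if len(frame) else 0,
        }

    try:
        metrics = evaluate_dataset(gt_maps, pred_maps,
                                   provenance={"config_hash": config.hash,
                                               "seed": config.seed})
    except Exception as exc:
        raise StageError(f"evaluate: {exc}") from exc
    metrics.to_json(out / "report.json")
    metrics.to_csv(out / "report.csv")
    report["metrics"] = metrics.summary()
    (out / "pipeline.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _write_overlay(mic, labels, path: Path) -> None:
    from PIL import Image
    Image.fromarray(eio.overlay(mic, labels)).save(path)
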