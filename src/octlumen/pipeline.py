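"""End-to-end orchestration: de-noising -> feature extraction -> edge
detection per frame, then stack-level quantification and output files.

Frames are processed independently (the tracer runs per B-scan; no
temporal smoothing).  A frame whose boundary detection raises is flagged
and its area recorded as missing; the run aborts only when more than
``max_failed_fraction`` of the frames fail.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dp_edge import DPParams, LumenBoundary, detect_boundary_circular
from .feature_extract import (FeatureParams, binarize, depth_gradient,
                              remove_small_objects, top_surface_mask)
from .io_types import AcquisitionGeometry, BScanStack, default_geometry, write_stack
from .preprocess import PreprocessParams, denoise
from .quantify import QuantReport, lumen_mask, stack_quantify

__all__ = ["PipelineConfig", "run_pipeline", "segment_frame"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Aggregate of all stage parameters plus run-level settings."""

    geometry: AcquisitionGeometry = field(default_factory=default_geometry)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    dp: DPParams = field(default_factory=DPParams)
    region_splits: tuple[float, ...] = (0.5,)
    max_failed_fraction: float = 0.2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region_splits"] = list(self.region_splits)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        if "geometry" in d:
            kwargs["geometry"] = AcquisitionGeometry(**d["geometry"])
        if "preprocess" in d:
            kwargs["preprocess"] = PreprocessParams(**d["preprocess"])
        if "features" in d:
            kwargs["features"] = FeatureParams(**d["features"])
        if "dp" in d:
            kwargs["dp"] = DPParams(**d["dp"])
        if "region_splits" in d:
            kwargs["region_splits"] = tuple(d["region_splits"])
        if "max_failed_fraction" in d:
            kwargs["max_failed_fraction"] = d["max_failed_fraction"]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def segment_frame(frame: np.ndarray, config: PipelineConfig) -> LumenBoundary:
    """Run the three-stage segmentation on one polar B-scan."""
    den = denoise(frame, config.preprocess)
    binary = binarize(den, config.features)
    binary = remove_small_objects(binary, config.features.min_object_area)
    masked, skipped = top_surface_mask(den, binary, config.features)
    if skipped:
        log.debug("frame: %d A-line(s) without foreground", len(skipped))
    grad = depth_gradient(masked)
    return detect_boundary_circular(grad, config.dp)


def run_pipeline(
    stack: BScanStack,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> tuple[list[LumenBoundary | None], QuantReport]:
    """Segment every frame of a pullback stack and quantify the lumen.

    Returns the per-frame boundaries (``None`` where detection failed)
    and the quantification report.  When ``out_dir`` is given, writes
    ``areas.csv``, ``report.json`` and ``masks.tiff`` there.
    """
    config = config or PipelineConfig()
    boundaries: list[LumenBoundary | None] = []
    for k in range(stack.n_frames):
        try:
            b = segment_frame(stack.frames[k], config)
            if not b.closed:
                log.warning("frame %d: boundary not closed across the seam", k)
            boundaries.append(b)
        except Exception as exc:  # per-frame failure is not fatal
            log.warning("frame %d: boundary detection failed (%s)", k, exc)
            boundaries.append(None)
    n_failed = sum(b is None for b in boundaries)
    if n_failed > config.max_failed_fraction * stack.n_frames:
        raise RuntimeError(
            f"boundary detection failed on {n_failed}/{stack.n_frames} frames"
        )
    report = stack_quantify(boundaries, stack.geometry, config.region_splits)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "areas.csv")
        report.to_json(out_dir / "report.json")
        masks = np.stack([
            lumen_mask(b, (stack.n_depth, stack.n_alines)).astype(float)
            if b is not None else np.zeros((stack.n_depth, stack.n_alines))
            for b in boundaries
        ])
        write_stack(masks, out_dir / "masks.tiff", bit_depth=8)
    return boundaries, report
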