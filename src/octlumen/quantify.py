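"""Geometric quantification: boundaries -> Cartesian cross-sections,
per-frame lumen areas, binary lumen masks and total lumen volume.

A-line ``i`` of a W-column frame points along ``theta_i = 2*pi*i/W``; the
traced depth index maps to a radius through the acquisition geometry.
The per-frame cross-section is the polygon of those (r, theta) vertices;
its area comes from the shoelace formula, which is exact for polygonal
boundaries and independent of image resolution.  Volume is the rectangle
rule, area times inter-frame spacing, matching the voxel semantics of a
stacked binary reconstruction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dp_edge import LumenBoundary
from .io_types import AcquisitionGeometry

__all__ = [
    "LumenPolygon",
    "QuantReport",
    "boundary_to_polygon",
    "cross_section_area",
    "lumen_mask",
    "stack_quantify",
]


@dataclass
class LumenPolygon:
    """Closed cross-section contour; ``vertices`` is (W, 2) in mm."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (n, 2)")


@dataclass
class RegionSummary:
    """Mean +/- SD of per-frame areas over a contiguous frame range."""

    start_frame: int
    end_frame: int  # exclusive
    mean_area: float
    sd_area: float
    n_frames: int


@dataclass
class QuantReport:
    """Per-frame areas (mm^2), summaries and total lumen volume (mm^3)."""

    per_frame_area: np.ndarray
    frame_spacing: float
    total_volume: float
    mean_area: float
    sd_area: float
    region_summaries: list[RegionSummary] = field(default_factory=list)
    n_failed_frames: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_frame_area"] = [None if not np.isfinite(a) else float(a)
                               for a in self.per_frame_area]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def areas_frame(self) -> pd.DataFrame:
        z = np.arange(len(self.per_frame_area)) * self.frame_spacing
        return pd.DataFrame({
            "frame": np.arange(len(self.per_frame_area)),
            "z_mm": z,
            "area_mm2": self.per_frame_area,
        })

    def to_csv(self, path) -> None:
        self.areas_frame().to_csv(path, index=False, float_format="%.9g")


def boundary_to_polygon(
    boundary: LumenBoundary, geometry: AcquisitionGeometry
) -> LumenPolygon:
    """Map a traced polar boundary to Cartesian vertices (mm).

    Vertex ``i``: angle ``2*pi*i/W``, radius ``offset + depth * pitch``.
    An open boundary still maps, with a warning — the polygon closes
    implicitly across the seam.
    """
    if not boundary.closed:
        warnings.warn("boundary is not closed across the seam", stacklevel=2)
    W = boundary.n_alines
    theta = 2.0 * np.pi * np.arange(W) / W
    r = geometry.radius_mm(boundary.depth_index)
    return LumenPolygon(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


def cross_section_area(polygon: LumenPolygon) -> float:
    """Polygon area (mm^2) by the shoelace formula, orientation-free."""
    v = polygon.vertices
    if v.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def lumen_mask(boundary: LumenBoundary, frame_shape: tuple[int, int]) -> np.ndarray:
    """Polar binary mask of the lumen: pixel (j, i) is lumen iff
    ``j < depth_index[i]``.  Column sums therefore equal the boundary
    rows exactly; intended for the stacked 3D binary export."""
    rows, cols = frame_shape
    if boundary.n_alines != cols:
        raise ValueError("boundary width does not match frame shape")
    depth_idx = np.arange(rows)[:, None]
    return depth_idx < boundary.depth_index[None, :]


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


def stack_quantify(
    boundaries: list[LumenBoundary | None],
    geometry: AcquisitionGeometry,
    region_splits: tuple[float, ...] = (0.5,),
) -> QuantReport:
    """Per-frame areas, total volume and regional summaries for a pullback.

    ``boundaries`` may contain ``None`` for frames where detection failed;
    those areas are NaN and are excluded from volume, mean and SD (the
    count is reported).  ``region_splits`` are pullback fractions cutting
    the stack into contiguous regions (default: proximal/distal halves).
    Volume = sum(area) * frame_spacing (rectangle rule); SD uses the n-1
    denominator.
    """
    if len(boundaries) == 0:
        raise ValueError("no boundaries")
    areas = np.full(len(boundaries), np.nan)
    for k, b in enumerate(boundaries):
        if b is None:
            continue
        areas[k] = cross_section_area(boundary_to_polygon(b, geometry))
    ok = np.isfinite(areas)
    mean, sd = _mean_sd(areas[ok])
    volume = float(np.nansum(areas) * geometry.frame_spacing)

    n = len(boundaries)
    cuts = [0] + [int(round(f * n)) for f in sorted(region_splits)] + [n]
    regions = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b <= a:
            continue
        seg = areas[a:b]
        seg_ok = seg[np.isfinite(seg)]
        m, s = _mean_sd(seg_ok)
        regions.append(RegionSummary(a, b, m, s, int(seg_ok.size)))
    return QuantReport(
        per_frame_area=areas,
        frame_spacing=geometry.frame_spacing,
        total_volume=volume,
        mean_area=mean,
        sd_area=sd,
        region_summaries=regions,
        n_failed_frames=int((~ok).sum()),
    )
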