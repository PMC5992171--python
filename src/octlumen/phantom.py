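"""Seeded synthetic pullback generator with analytic ground truth.

Real endoscopic OCT pullbacks of airways are not bundled with this
package, so a phantom emulates their salient structure: a dark lumen
around the probe, a bright attenuating tissue band starting at a known
radius profile, bright sheath-reflection rings at fixed shallow depth,
multiplicative gamma speckle (mean 1) and additive Gaussian background
noise.  The radius profile ``r(theta, z)`` is a free function of the
angular and pullback fractions; presets cover a straight airway
(cylinder), an oval airway (ellipse), a focal narrowing (stenosis) and a
detached tissue flap bulging into the lumen.

The ground truth carries the analytic polar areas ``0.5 * integral of
r^2 dtheta`` (evaluated at the A-line sampling) and the exact surface
rows, giving the quantification stage an oracle that shares no code with
the segmentation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .io_types import AcquisitionGeometry, BScanStack, default_geometry
from .quantify import QuantReport, RegionSummary, _mean_sd

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "cylinder",
    "ellipse",
    "stenosis",
    "flap",
    "generate_phantom",
    "ground_truth_report",
    "PRESETS",
]

RadiusFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


def cylinder(r: float = 1.2) -> RadiusFn:
    """Constant radius r (mm) — a straight, uniform airway."""
    return lambda theta_frac, z_frac: np.broadcast_to(
        float(r), np.broadcast_shapes(np.shape(theta_frac), np.shape(z_frac))
    ).copy()


def ellipse(a: float = 1.4, b: float = 1.0) -> RadiusFn:
    """Elliptical cross-section with semi-axes a, b (mm)."""
    def fn(theta_frac, z_frac):
        th = 2.0 * np.pi * np.asarray(theta_frac)
        return a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)
    return fn


def stenosis(
    r: float = 1.2,
    depth_of_narrowing: float = 0.5,
    z_center: float = 0.5,
    z_width: float = 0.1,
) -> RadiusFn:
    """Axial narrowing: radius dips by the given fraction around z_center.

    The dip is a Gaussian bump in the pullback fraction with standard
    deviation ``z_width``; ``depth_of_narrowing=0.5`` halves the radius
    (quarters the area) at the center of the stenosis.
    """
    def fn(theta_frac, z_frac):
        z = np.asarray(z_frac, dtype=float)
        dip = depth_of_narrowing * np.exp(-0.5 * ((z - z_center) / z_width) ** 2)
        return r * (1.0 - dip) + np.zeros(np.shape(theta_frac))
    return fn


def flap(
    r: float = 1.2,
    angular_extent: float = 0.25,
    lift: float = 0.15,
) -> RadiusFn:
    """Detached tissue flap: a raised-cosine intrusion of height ``lift``
    (mm) over an ``angular_extent`` fraction of the circumference.

    A single-row-per-A-line tracer can only follow surfaces whose slope
    stays within one depth pixel per A-line; the default lift/extent obey
    that limit (steeper, overhanging flaps are outside the model).
    """
    def fn(theta_frac, z_frac):
        t = np.asarray(theta_frac, dtype=float)
        # center the flap at theta_frac = 0.5
        u = (t - 0.5) / angular_extent
        bump = np.where(np.abs(u) <= 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * u)), 0.0)
        return r - lift * bump + np.zeros(np.shape(z_frac))
    return fn


PRESETS: dict[str, Callable[..., RadiusFn]] = {
    "cylinder": cylinder,
    "ellipse": ellipse,
    "stenosis": stenosis,
    "flap": flap,
}


@dataclass
class PhantomSpec:
    """Everything needed to synthesize one pullback stack.

    Noise is off when ``speckle_shape`` is None and
    ``background_noise_sd`` is 0; the same spec and seed always produce a
    bit-identical stack.
    """

    n_frames: int = 150
    n_alines: int = 256
    n_depth: int = 180
    geometry: AcquisitionGeometry = field(default_factory=default_geometry)
    lumen_radius_fn: RadiusFn = field(default_factory=cylinder)
    tissue_thickness: float = 0.3  # mm
    tissue_reflectivity: float = 0.8
    attenuation: float = 2.0  # 1/mm, single-pass intensity decay in tissue
    speckle_shape: float | None = None  # gamma shape; None = speckle off
    sheath_ring_rows: tuple[int, ...] = (4, 7)
    sheath_ring_intensity: float = 0.9
    background_noise_sd: float = 0.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Analytic truth for a generated phantom."""

    boundary_rows: np.ndarray  # (n_frames, n_alines) int surface rows
    radii: np.ndarray  # (n_frames, n_alines) exact radii, mm
    per_frame_area: np.ndarray  # analytic polar areas, mm^2
    total_volume: float  # mm^3
    tissue_mask: np.ndarray  # (n_frames, n_depth, n_alines) bool, noise-free


def generate_phantom(spec: PhantomSpec) -> tuple[BScanStack, GroundTruth]:
    """Synthesize a pullback stack and its ground truth.

    Per frame and A-line the surface row is ``round((r - offset)/pitch)``;
    intensity is 0 above it, ``reflectivity * exp(-attenuation * depth)``
    through the tissue band and 0 beyond.  Sheath rings are pasted at
    fixed rows, then speckle, additive noise and clipping are applied.
    """
    geo = spec.geometry
    F, D, W = spec.n_frames, spec.n_depth, spec.n_alines
    theta_frac = (np.arange(W) / W)[None, :]
    z_frac = (np.arange(F) / max(F - 1, 1))[:, None]
    r = np.asarray(spec.lumen_radius_fn(theta_frac, z_frac), dtype=float)
    r = np.broadcast_to(r, (F, W))
    if np.any(r < geo.probe_offset_radius):
        raise ValueError("lumen radius smaller than the probe offset")
    rows = np.rint((r - geo.probe_offset_radius) / geo.radial_pixel_pitch).astype(int)
    t_rows = int(round(spec.tissue_thickness / geo.radial_pixel_pitch))
    if np.any(rows + t_rows >= D):
        raise ValueError("lumen outside field of view")

    rel = np.arange(D)[None, :, None] - rows[:, None, :]  # (F, D, W)
    tissue = (rel >= 0) & (rel < t_rows)
    decay = np.exp(-spec.attenuation * np.clip(rel, 0, None) * geo.radial_pixel_pitch)
    frames = np.where(tissue, spec.tissue_reflectivity * decay, 0.0)
    for ring in spec.sheath_ring_rows:
        frames[:, ring, :] = np.maximum(frames[:, ring, :], spec.sheath_ring_intensity)

    rng = np.random.default_rng(spec.seed)
    if spec.speckle_shape is not None:
        k = float(spec.speckle_shape)
        frames = frames * rng.gamma(k, 1.0 / k, size=frames.shape)
    if spec.background_noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.background_noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, 1.0)

    dtheta = 2.0 * np.pi / W
    areas = 0.5 * (r ** 2).sum(axis=1) * dtheta
    truth = GroundTruth(
        boundary_rows=rows,
        radii=r,
        per_frame_area=areas,
        total_volume=float(areas.sum() * geo.frame_spacing),
        tissue_mask=tissue,
    )
    return BScanStack(frames=frames, geometry=geo), truth


def ground_truth_report(
    truth: GroundTruth,
    geometry: AcquisitionGeometry,
    region_splits: tuple[float, ...] = (0.5,),
) -> QuantReport:
    """QuantReport built from the analytic radii (no segmentation)."""
    areas = truth.per_frame_area
    mean, sd = _mean_sd(areas)
    n = len(areas)
    cuts = [0] + [int(round(f * n)) for f in sorted(region_splits)] + [n]
    regions = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b <= a:
            continue
        m, s = _mean_sd(areas[a:b])
        regions.append(RegionSummary(a, b, m, s, b - a))
    return QuantReport(
        per_frame_area=areas.copy(),
        frame_spacing=geometry.frame_spacing,
        total_volume=float(areas.sum() * geometry.frame_spacing),
        mean_area=mean,
        sd_area=sd,
        region_summaries=regions,
        n_failed_frames=0,
    )
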