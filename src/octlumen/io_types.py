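"""Data model and I/O for endoscopic OCT pullback stacks.

A pullback acquisition is an ordered set of polar-coordinate B-scans.
Each B-scan is stored as a 2D array with rows = depth samples along an
A-line (index ``j``, 0 nearest the probe) and columns = angular A-line
positions (index ``i``).  Intensities are normalized to [0, 1] at load
time so that downstream thresholds are independent of the acquisition
bit depth.

The physical mapping from pixel indices to geometry is::

    radius(j) = probe_offset_radius + j * radial_pixel_pitch   [mm]
    theta(i)  = 2 * pi * i / n_alines                          [rad]
    z(frame)  = frame * frame_spacing                          [mm]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "AcquisitionGeometry",
    "BScanStack",
    "derive_geometry",
    "default_geometry",
    "load_bscan_stack",
    "write_stack",
    "validate_bscan",
]

_MIN_FRAME_DIM = 8


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical scan geometry of a rotational pullback acquisition.

    Parameters
    ----------
    radial_pixel_pitch : float
        Length of one depth pixel, mm/px.
    probe_offset_radius : float
        Radial distance from the rotation axis to depth index 0, mm.
    frame_spacing : float
        Pullback distance between consecutive B-scans, mm.
    pullback_speed : float, optional
        Probe translation speed, mm/s.
    frame_rate : float, optional
        B-scan acquisition rate, frames/s.
    rotation_speed : float, optional
        Probe rotation speed, rpm (informational; one frame per turn).
    """

    radial_pixel_pitch: float
    probe_offset_radius: float
    frame_spacing: float
    pullback_speed: float | None = None
    frame_rate: float | None = None
    rotation_speed: float | None = None

    def __post_init__(self) -> None:
        if self.radial_pixel_pitch <= 0:
            raise ValueError("radial_pixel_pitch must be > 0")
        if self.probe_offset_radius < 0:
            raise ValueError("probe_offset_radius must be >= 0")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be > 0")
        if self.pullback_speed is not None and self.frame_rate is not None:
            expected = self.pullback_speed / self.frame_rate
            if not np.isclose(self.frame_spacing, expected, rtol=1e-9, atol=1e-12):
                raise ValueError(
                    f"frame_spacing {self.frame_spacing} inconsistent with "
                    f"pullback_speed/frame_rate = {expected}"
                )
        if self.rotation_speed is not None and self.frame_rate is not None:
            if not np.isclose(self.frame_rate, self.rotation_speed / 60.0):
                warnings.warn(
                    f"frame_rate {self.frame_rate} fps does not match "
                    f"rotation_speed {self.rotation_speed} rpm "
                    f"({self.rotation_speed / 60.0} fps)",
                    stacklevel=2,
                )

    def radius_mm(self, depth_index):
        """Radial position (mm) of one or more depth indices."""
        return self.probe_offset_radius + np.asarray(depth_index) * self.radial_pixel_pitch


def derive_geometry(
    pullback_speed: float,
    frame_rate: float,
    rotation_speed: float | None = None,
    *,
    radial_pixel_pitch: float = 0.01,
    probe_offset_radius: float = 0.3,
) -> AcquisitionGeometry:
    """Build an :class:`AcquisitionGeometry` from acquisition settings.

    ``frame_spacing = pullback_speed / frame_rate``.  If ``rotation_speed``
    is given and ``rotation_speed / 60`` disagrees with ``frame_rate`` a
    warning is emitted (one frame is acquired per probe revolution).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    if pullback_speed < 0:
        raise ValueError("pullback_speed must be >= 0")
    spacing = pullback_speed / frame_rate
    if spacing <= 0:
        # A zero-speed pullback has no inter-frame distance; keep a positive
        # sentinel out of the constructor and let the caller decide.
        raise ValueError("pullback_speed 0 gives frame_spacing 0, which is invalid")
    return AcquisitionGeometry(
        radial_pixel_pitch=radial_pixel_pitch,
        probe_offset_radius=probe_offset_radius,
        frame_spacing=spacing,
        pullback_speed=pullback_speed,
        frame_rate=frame_rate,
        rotation_speed=rotation_speed,
    )


def default_geometry() -> AcquisitionGeometry:
    """Fixture geometry: 10 um radial pitch, 0.3 mm sheath offset,
    5 mm/s pullback at 25 fps (0.2 mm inter-frame distance)."""
    return derive_geometry(5.0, 25.0, 1500.0)


def validate_bscan(frame: np.ndarray) -> np.ndarray:
    """Check one polar B-scan: 2D, >= 8x8, intensities in [0, 1]."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"B-scan must be 2D, got shape {frame.shape}")
    if frame.shape[0] < _MIN_FRAME_DIM or frame.shape[1] < _MIN_FRAME_DIM:
        raise ValueError(f"B-scan must be at least 8x8, got {frame.shape}")
    if frame.min() < 0 or frame.max() > 1:
        raise ValueError("B-scan intensities must lie in [0, 1]")
    return frame


@dataclass
class BScanStack:
    """Ordered pullback stack of equally shaped polar B-scans.

    ``frames`` has shape ``(n_frames, n_depth, n_alines)`` with float
    intensities in [0, 1].
    """

    frames: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise ValueError("no frames")
        validate_bscan(self.frames[0])
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("stack intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_depth(self) -> int:
        return self.frames.shape[1]

    @property
    def n_alines(self) -> int:
        return self.frames.shape[2]

    def z_positions(self) -> np.ndarray:
        """Pullback position (mm) of every frame."""
        return np.arange(self.n_frames) * self.geometry.frame_spacing

    def with_frames(self, frames: np.ndarray) -> "BScanStack":
        return BScanStack(frames=frames, geometry=self.geometry)


def _read_frames(path: Path) -> list[np.ndarray]:
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".tif", ".tiff", ".png"}
        )
        if not files:
            raise ValueError("no frames")
        frames = []
        for f in files:
            if f.suffix.lower() in {".tif", ".tiff"}:
                arr = tifffile.imread(f)
            else:
                arr = iio.imread(f)
            if arr.ndim == 3:  # RGB(A) PNG -> luminance via first channel
                arr = arr[..., 0]
            frames.append(arr)
        return frames
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return list(arr)


def load_bscan_stack(path, geometry: AcquisitionGeometry) -> BScanStack:
    """Load a pullback stack from a multi-page TIFF or a frame directory.

    Integer pixels are divided by the dtype maximum (8/16-bit); floating
    input is divided by the stack maximum.  Frame order is page order for
    TIFF, lexicographic filename order for directories.
    """
    path = Path(path)
    frames = _read_frames(path)
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch across frames: {sorted(shapes)}")
    stack = np.stack(frames)
    if np.issubdtype(stack.dtype, np.integer):
        stack = stack.astype(float) / np.iinfo(stack.dtype).max
    else:
        stack = stack.astype(float)
        m = stack.max()
        if m > 0:
            stack = stack / m
    return BScanStack(frames=np.clip(stack, 0.0, 1.0), geometry=geometry)


def write_stack(frames: np.ndarray, path, bit_depth: int = 8) -> None:
    """Write a [0, 1] float stack as a multi-page 8- or 16-bit TIFF.

    Rounds to the dtype grid, so ``write_stack(load_bscan_stack(p).frames)``
    reproduces integer input bit-exactly.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    maxval = np.iinfo(dtype).max
    arr = np.asarray(frames, dtype=float)
    out = np.clip(np.rint(arr * maxval), 0, maxval).astype(dtype)
    tifffile.imwrite(Path(path), out, photometric="minisblack")
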