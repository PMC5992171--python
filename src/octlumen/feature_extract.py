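"""Feature extraction: binarization, artifact removal, top-surface masking
and the depth-gradient image fed to the boundary tracer.

The stage isolates the inner (medial) surface of the airway wall.
Binarization gives the general wall shape; small connected components
(sheath reflections, debris) are removed; everything deeper than a margin
below the first tissue pixel of each A-line is zeroed so that only the
innermost lumen surface can attract the tracer; finally the rising-edge
depth derivative turns the dark-to-bright lumen/tissue transition into a
bright ridge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "FeatureParams",
    "binarize",
    "remove_small_objects",
    "top_surface_mask",
    "depth_gradient",
]


@dataclass(frozen=True)
class FeatureParams:
    """Knobs of the feature-extraction stage.

    threshold : "otsu" or a fixed scalar in (0, 1).
    min_object_area : components smaller than this (pixels) are removed.
    surface_margin : pixels kept below the detected top surface.
    sheath_exclusion_depth : rows at the top of every A-line forced to
        background before thresholding (guard band for sheath rings).
    """

    threshold: str | float = "otsu"
    min_object_area: int = 200
    surface_margin: int = 30
    sheath_exclusion_depth: int = 10

    def __post_init__(self) -> None:
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")
        if self.surface_margin < 1:
            raise ValueError("surface_margin must be >= 1")
        if self.sheath_exclusion_depth < 0:
            raise ValueError("sheath_exclusion_depth must be >= 0")
        if not (self.threshold == "otsu" or 0 < float(self.threshold) < 1):
            raise ValueError("threshold must be 'otsu' or a scalar in (0,1)")


def binarize(frame: np.ndarray, params: FeatureParams | None = None) -> np.ndarray:
    """Threshold a denoised B-scan into a boolean tissue mask.

    The threshold (Otsu by default) is computed on the rows below the
    sheath guard band; pixels >= threshold are foreground.  A constant
    frame has no Otsu threshold — it yields an all-background mask and a
    warning rather than an exception.
    """
    params = params or FeatureParams()
    frame = np.asarray(frame, dtype=float)
    d = params.sheath_exclusion_depth
    body = frame[d:, :]
    if body.size == 0 or np.ptp(body) == 0:
        warnings.warn("constant frame: threshold undefined, returning empty mask",
                      stacklevel=2)
        return np.zeros(frame.shape, dtype=bool)
    if params.threshold == "otsu":
        thr = threshold_otsu(body)
    else:
        thr = float(params.threshold)
    mask = frame >= thr
    mask[:d, :] = False
    return mask


def _wrap_merge_labels(labels: np.ndarray) -> np.ndarray:
    """Union labels that touch across the angular seam (8-connectivity)."""
    n = labels.max()
    parent = np.arange(n + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    left, right = labels[:, 0], labels[:, -1]
    rows = labels.shape[0]
    for j in range(rows):
        if right[j] == 0:
            continue
        for dj in (-1, 0, 1):
            k = j + dj
            if 0 <= k < rows and left[k] != 0:
                union(int(right[j]), int(left[k]))
    roots = np.array([find(x) for x in range(n + 1)])
    return roots[labels]


def remove_small_objects(binary: np.ndarray, min_object_area: int) -> np.ndarray:
    """Drop 8-connected foreground components smaller than ``min_object_area``.

    Connectivity wraps around the angular (column) direction because the
    B-scan is a cylinder cut open; components of size >= the limit are kept.
    """
    binary = np.asarray(binary, dtype=bool)
    labels = label(binary, connectivity=2)
    labels = _wrap_merge_labels(labels)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts >= min_object_area
    return keep[labels]


def top_surface_mask(
    frame: np.ndarray,
    binary: np.ndarray,
    params: FeatureParams | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Zero everything deeper than ``surface_margin`` below the top surface.

    For each A-line the top surface is the shallowest foreground row of
    ``binary``; intensities deeper than ``surface + margin`` are set to 0
    so that deeper interfaces (detached tissue layers, the far wall)
    cannot attract the tracer.  A-lines without any foreground are left
    unchanged; their indices are returned for reporting.
    """
    params = params or FeatureParams()
    frame = np.asarray(frame, dtype=float)
    binary = np.asarray(binary, dtype=bool)
    out = frame.copy()
    any_fg = binary.any(axis=0)
    if not any_fg.any():
        warnings.warn("empty binary mask: frame returned unmasked", stacklevel=2)
        return out, list(range(frame.shape[1]))
    surface = np.argmax(binary, axis=0)  # first True per column
    depth_idx = np.arange(frame.shape[0])[:, None]
    cut = surface[None, :] + params.surface_margin
    mask = (depth_idx > cut) & any_fg[None, :]
    out[mask] = 0.0
    return out, np.flatnonzero(~any_fg).tolist()


def depth_gradient(frame: np.ndarray) -> np.ndarray:
    """Rising-edge depth derivative, rescaled to [0, 1].

    ``G[j] = max(I[j] - I[j-1], 0)`` with row 0 set to zero: the response
    to a dark-to-bright transition sits on the first bright pixel, which
    is the depth index the radius map assigns to the tissue surface.
    Falling edges are clipped so the far side of the tissue band stays
    dark to the tracer.
    """
    frame = np.asarray(frame, dtype=float)
    grad = np.zeros_like(frame)
    grad[1:, :] = frame[1:, :] - frame[:-1, :]
    np.clip(grad, 0.0, None, out=grad)
    m = grad.max()
    if m > 0:
        grad /= m
    return grad
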