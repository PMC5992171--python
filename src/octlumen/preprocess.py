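"""De-noising of polar B-scans: speckle suppression and A-line equalization.

Speckle — the multiplicative interference noise of coherent imaging — is
suppressed with a 2D median filter.  Strong specular reflections from the
transparent protective sheath make some A-lines far brighter than others;
normalizing every A-line (column) to a common intensity sum flattens that
artifact before binarization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PreprocessParams", "denoise", "median_despeckle", "normalize_alines"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the de-noising stage.

    median_kernel : odd square window size in pixels.
    normalize_alines : equalize per-column intensity sums.
    target_aline_sum : common column sum; ``None`` means the mean column
        sum of the frame ("stack-mean" behaviour, brightness preserving).
    """

    median_kernel: int = 5
    normalize_alines: bool = True
    target_aline_sum: float | None = None

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")


def median_despeckle(frame: np.ndarray, kernel: int) -> np.ndarray:
    """Square median filter; reflect padding in depth, wrap across columns.

    The angular direction of a polar B-scan is circular, so the filter
    wraps across the left/right image seam.
    """
    frame = np.asarray(frame, dtype=float)
    if kernel > min(frame.shape):
        raise ValueError(
            f"frame too small: shape {frame.shape} for kernel {kernel}"
        )
    if kernel == 1:
        return frame.copy()
    # rank filters take a single border mode, so wrap the circular
    # (column) axis by explicit padding and reflect the depth axis
    half = kernel // 2
    padded = np.pad(frame, ((0, 0), (half, half)), mode="wrap")
    out = ndimage.median_filter(padded, size=kernel, mode="reflect")
    return out[:, half:-half]


def normalize_alines(frame: np.ndarray, target: float | None = None) -> np.ndarray:
    """Scale each column so its intensity sum equals ``target``.

    ``target=None`` uses the mean column sum of the frame.  Columns whose
    sum is zero cannot be scaled; they are left unchanged and logged.
    """
    frame = np.asarray(frame, dtype=float)
    sums = frame.sum(axis=0)
    if target is None:
        target = float(sums.mean())
    scale = np.ones_like(sums)
    nonzero = sums > 0
    scale[nonzero] = target / sums[nonzero]
    n_dark = int((~nonzero).sum())
    if n_dark:
        log.info("normalize_alines: %d zero-sum A-line(s) left unscaled", n_dark)
    return frame * scale[None, :]


def denoise(frame: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Median-despeckle then (optionally) equalize A-line sums.

    The result is divided by its maximum and clipped back to [0, 1], so
    the output is a valid B-scan whatever scaling normalization applied.
    """
    params = params or PreprocessParams()
    out = median_despeckle(frame, params.median_kernel)
    if params.normalize_alines:
        out = normalize_alines(out, params.target_aline_sum)
    m = out.max()
    if m > 0:
        out = out / m
    return np.clip(out, 0.0, 1.0)
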