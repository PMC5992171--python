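"""Agreement analysis between two segmentations of the same pullback.

Bland-Altman analysis plots the per-frame difference of two area series
against their per-frame mean and summarizes agreement by the bias (mean
difference) and the 95% limits of agreement, bias +/- 1.96 * SD(diff).
The bias is also expressed as a percentage of the grand mean area so it
can be read as a relative systematic error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BlandAltmanResult",
    "summarize_areas",
    "bland_altman",
    "load_reference_segmentation",
    "plot_bland_altman",
]


@dataclass
class BlandAltmanResult:
    per_frame_diff: np.ndarray  # A - B, mm^2
    per_frame_mean: np.ndarray  # (A + B) / 2, mm^2
    bias: float  # mean difference, mm^2
    loa_low: float  # bias - 1.96 * SD(diff)
    loa_high: float  # bias + 1.96 * SD(diff)
    percent_bias: float  # 100 * bias / grand mean of per_frame_mean

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_frame_diff"] = [float(x) for x in self.per_frame_diff]
        d["per_frame_mean"] = [float(x) for x in self.per_frame_mean]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def summarize_areas(areas) -> tuple[float, float]:
    """Sample mean and SD (n-1 denominator) of a per-frame area series."""
    areas = np.asarray(areas, dtype=float)
    if areas.size < 2:
        raise ValueError("need at least 2 areas")
    return float(areas.mean()), float(areas.std(ddof=1))


def bland_altman(areas_a, areas_b) -> BlandAltmanResult:
    """Bland-Altman agreement between two frame-aligned area series.

    Differences are A - B; limits of agreement use the fixed normal 1.96
    multiplier.  ``percent_bias`` divides the bias by the grand mean of
    the per-frame means (0 when the bias is exactly 0).
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch between the two series")
    if a.size < 2:
        raise ValueError("need at least 2 frames")
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    grand = float(mean.mean())
    if bias == 0.0:
        pct = 0.0
    else:
        pct = 100.0 * bias / grand
    return BlandAltmanResult(
        per_frame_diff=diff,
        per_frame_mean=mean,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        percent_bias=pct,
    )


def load_reference_segmentation(path) -> np.ndarray:
    """Read a per-frame area table (columns ``frame``, ``area_mm2``).

    Manual tracings from external tools arrive as such tables.  Frames
    must be contiguous from their minimum; the areas are returned ordered
    by frame index.
    """
    df = pd.read_csv(path)
    for col in ("frame", "area_mm2"):
        if col not in df.columns:
            raise ValueError(f"missing column '{col}'")
    if not np.issubdtype(df["area_mm2"].dtype, np.number):
        raise ValueError("area_mm2 column is not numeric")
    df = df.sort_values("frame")
    frames = df["frame"].to_numpy()
    if not np.array_equal(frames, np.arange(frames.min(), frames.min() + len(frames))):
        raise ValueError("non-contiguous frames")
    return df["area_mm2"].to_numpy(dtype=float)


def plot_bland_altman(result: BlandAltmanResult, path) -> None:
    """Scatter of difference vs mean with dashed bias and LoA lines (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.per_frame_mean, result.per_frame_diff, s=12, alpha=0.7)
    for y in (result.bias, result.loa_low, result.loa_high):
        ax.axhline(y, linestyle="--", color="k", linewidth=1)
    ax.set_xlabel("mean area of the two segmentations (mm$^2$)")
    ax.set_ylabel("difference in area (mm$^2$)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
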