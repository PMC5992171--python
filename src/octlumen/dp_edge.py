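"""Dynamic-programming minimum-cost boundary tracer.

The inner lumen surface appears in the gradient image as a bright,
roughly horizontal ridge: one depth row per A-line column.  Tracing it
is cast as a shortest-path problem over columns.  A path visits one row
per column, moving at most one row between neighbours (8-connectivity),
and pays for each transition

    w(a, b) = 2 * max(I) - a - b

where ``a`` and ``b`` are the gradient intensities of the two pixels and
``max(I)`` the image maximum, so bright transitions are cheap.  Diagonal
moves are scaled by ``alpha`` (default sqrt(2), the geometric step-length
ratio).  Accumulated costs are filled left to right:

    Cost(i, j) = min over j' in {j-1, j, j+1} of
                 m(j') * w(I(i-1, j'), I(i, j)) + Cost(i-1, j')

with ``m = alpha`` for diagonal predecessors and 1 for straight ones,
seeded at column 0 with ``Cost(0, j) = 2 * (max(I) - I(0, j))``.  The
boundary is read back from the minimum of the last column through stored
backpointers.

A B-scan is cylindrical: to keep the traced path connected across the
image seam, the image is duplicated and concatenated at both ends, the
tracer runs on the triple-width image, and the middle copy is returned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DPParams",
    "CostMatrix",
    "LumenBoundary",
    "pixel_cost",
    "compute_cost_matrix",
    "trace_min_cost_path",
    "detect_boundary_circular",
]


@dataclass(frozen=True)
class DPParams:
    """alpha: diagonal transition scale factor (>= 1).
    pad_mode: "full-duplicate" (triple-width circular padding) or "none".
    """

    alpha: float = math.sqrt(2.0)
    pad_mode: str = "full-duplicate"

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.pad_mode not in ("full-duplicate", "none"):
            raise ValueError("pad_mode must be 'full-duplicate' or 'none'")


@dataclass
class CostMatrix:
    """Accumulated DP costs and predecessor offsets.

    ``cost[j, i]`` is the minimum cost of any admissible path ending at
    row j of column i; ``backpointer[j, i]`` is the row offset (-1, 0, +1)
    of the predecessor in column i-1 (column 0 is the sentinel 0).
    """

    cost: np.ndarray
    backpointer: np.ndarray


@dataclass
class LumenBoundary:
    """Traced inner surface: one depth row per A-line column.

    ``closed`` marks whether the two seam-adjacent ends meet within one
    row, i.e. whether the contour closes around the lumen.
    """

    depth_index: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.depth_index = np.asarray(self.depth_index, dtype=int)
        steps = np.abs(np.diff(self.depth_index))
        if steps.size and steps.max() > 1:
            raise ValueError("boundary violates the +/-1 step constraint")

    @property
    def n_alines(self) -> int:
        return self.depth_index.size


def pixel_cost(a: float, b: float, max_I: float) -> float:
    """Transition cost between two gradient intensities: 2*max(I) - a - b."""
    return 2.0 * max_I - a - b


def compute_cost_matrix(gradient: np.ndarray, params: DPParams | None = None) -> CostMatrix:
    """Fill the accumulated-cost table column by column (left to right).

    Ties between predecessors break straight (0) first, then up (-1),
    then down (+1), which keeps flat boundaries flat.
    """
    params = params or DPParams()
    G = np.asarray(gradient, dtype=float)
    if G.ndim != 2:
        raise ValueError("gradient must be 2D")
    D, W = G.shape
    if W < 2:
        raise ValueError("gradient needs at least 2 columns")
    M = float(G.max())
    alpha = params.alpha

    cost = np.empty((D, W))
    back = np.zeros((D, W), dtype=np.int8)
    cost[:, 0] = 2.0 * (M - G[:, 0])
    for i in range(1, W):
        gp = G[:, i - 1]
        cp = cost[:, i - 1]
        base = 2.0 * M - G[:, i]  # w(a, b) = base - a
        best = (base - gp) + cp  # straight predecessor
        bp = np.zeros(D, dtype=np.int8)
        up = alpha * (base[1:] - gp[:-1]) + cp[:-1]  # predecessor j-1
        take = up < best[1:]
        best[1:][take] = up[take]
        bp[1:][take] = -1
        down = alpha * (base[:-1] - gp[1:]) + cp[1:]  # predecessor j+1
        take = down < best[:-1]
        best[:-1][take] = down[take]
        bp[:-1][take] = 1
        cost[:, i] = best
        back[:, i] = bp
    return CostMatrix(cost=cost, backpointer=back)


def trace_min_cost_path(costs: CostMatrix) -> LumenBoundary:
    """Read the boundary back from the cost table.

    Starts at the minimum of the right-most column (smallest row index on
    ties — np.argmin's convention) and follows backpointers to column 0.
    """
    cost, back = costs.cost, costs.backpointer
    D, W = cost.shape
    j = int(np.argmin(cost[:, -1]))
    path = np.empty(W, dtype=int)
    path[-1] = j
    for i in range(W - 1, 0, -1):
        j = j + int(back[j, i])
        path[i - 1] = j
    return LumenBoundary(depth_index=path,
                         closed=abs(int(path[0]) - int(path[-1])) <= 1)


def detect_boundary_circular(
    gradient: np.ndarray, params: DPParams | None = None
) -> LumenBoundary:
    """Trace the boundary with circular (seam-aware) padding.

    With ``pad_mode='full-duplicate'`` the W-column gradient becomes the
    3W-column image [G|G|G]; the tracer runs on that and the middle copy
    is returned, so the path may cross the seam freely.  The ``closed``
    flag records whether the returned ends meet within one row; an open
    contour triggers a warning but is still returned.
    """
    params = params or DPParams()
    G = np.asarray(gradient, dtype=float)
    if G.ndim != 2 or G.shape[1] < 8:
        raise ValueError("gradient must be 2D with at least 8 columns")
    W = G.shape[1]
    if params.pad_mode == "full-duplicate":
        padded = np.concatenate([G, G, G], axis=1)
        full = trace_min_cost_path(compute_cost_matrix(padded, params))
        depth = full.depth_index[W:2 * W]
    else:
        depth = trace_min_cost_path(compute_cost_matrix(G, params)).depth_index
    closed = abs(int(depth[0]) - int(depth[-1])) <= 1
    if not closed:
        warnings.warn("traced boundary does not close across the seam",
                      stacklevel=2)
    return LumenBoundary(depth_index=depth, closed=closed)
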