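"""Boundary tracing and digital arc length.

A single boundary-walk primitive backs both nuclear circularity and the
envelope continuity index, so that the perimeter in the denominator of the
continuity index and the perimeter in the circularity formula are always the
same number for the same mask.

The walk is a Moore-neighbour trace of the 8-connected outer boundary of a
mask, oriented counter-clockwise (in conventional x-right / y-up terms) and
started at the topmost-then-leftmost boundary pixel. Arc length accrues per
step; with ``calibrated=True`` (default) axial and diagonal steps are
weighted 0.948 and 1.340 — the classical Kulpa calibration that removes the
systematic ~5% overestimate of the naive 1 / √2 weighting on smooth,
isotropically oriented contours (a digital circle of radius 50 px comes out
within a fraction of a percent of 2πr). The raw 1 / √2 weights remain
available for exact step-count arithmetic on axis-aligned shapes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["trace_boundary", "step_lengths", "boundary_path_and_arcs", "KULPA_AXIAL", "KULPA_DIAGONAL"]

# Kulpa (1977) corrected step weights: E[estimate/truth] = 1 for straight
# segments of uniformly random orientation, hence near-exact for circles.
KULPA_AXIAL = 0.948
KULPA_DIAGONAL = 0.948 * np.sqrt(2.0)

# Moore neighbourhood in clockwise order starting East, in (drow, dcol);
# rows grow downward, so clockwise in array indices is counter-clockwise
# on a conventional y-up plot.
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_DIR_INDEX = {d: i for i, d in enumerate(_MOORE)}


def _single_component(mask: np.ndarray) -> None:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n != 1:
        raise ValueError(f"mask must be a single 8-connected component, found {n}")


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the closed outer boundary of a single-component boolean mask.

    Returns an (N, 2) integer array of (row, col) boundary pixel
    coordinates; the path is closed implicitly (last pixel is a neighbour
    of the first, the start pixel is not repeated). Raises ``ValueError``
    for an empty or multi-component mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    _single_component(mask)

    # pad so neighbour lookups never leave the array
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    # topmost, then leftmost foreground pixel is on the boundary
    top = rows.min()
    start = (top, cols[rows == top].min())

    if mask.sum() == 1:
        return np.array([[start[0] - 1, start[1] - 1]])

    path = [start]
    # backtrack entering direction: we arrived at start coming from the
    # pixel above it (guaranteed background because start is topmost)
    prev_dir = _DIR_INDEX[(-1, 0)]  # direction start -> pixel above
    cur = start
    while True:
        found = False
        # scan Moore neighbours clockwise, starting just after backtrack
        for k in range(1, 9):
            d = _MOORE[(prev_dir + k) % 8]
            nxt = (cur[0] + d[0], cur[1] + d[1])
            if padded[nxt]:
                # new backtrack = direction from nxt back to cur
                prev_dir = _DIR_INDEX[(-d[0], -d[1])]
                cur = nxt
                found = True
                break
        if not found:  # isolated pixel already handled; defensive
            break
        if cur == start and len(path) > 1:
            break
        path.append(cur)

    out = np.array(path, dtype=int)
    out -= 1  # undo padding offset
    return out


def step_lengths(path: np.ndarray, *, calibrated: bool = True, close: bool = True) -> np.ndarray:
    """Per-step digital lengths along a traced pixel path (in pixels).

    Step i is the move from path[i] to path[i+1]; with ``close=True`` a
    final step from the last pixel back to the first is appended, so the
    sum is the closed perimeter.
    """
    w_ax = KULPA_AXIAL if calibrated else 1.0
    w_di = KULPA_DIAGONAL if calibrated else np.sqrt(2.0)
    if len(path) == 1:
        return np.array([w_ax])  # degenerate single-pixel "loop"
    pts = np.vstack([path, path[:1]]) if close else path
    d = np.abs(np.diff(pts, axis=0))
    diag = (d[:, 0] == 1) & (d[:, 1] == 1)
    return np.where(diag, w_di, w_ax)


def boundary_path_and_arcs(
    mask: np.ndarray, pixel_size: float, *, calibrated: bool = True
) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed boundary path with cumulative arc positions in µm.

    Returns ``(path, arc_um, perimeter_um)`` where ``path`` has shape
    (N, 2), ``arc_um`` has shape (N,) with ``arc_um[0] == 0`` strictly
    increasing, and ``perimeter_um`` includes the closing step back to the
    start pixel.
    """
    path = trace_boundary(mask)
    steps = step_lengths(path, calibrated=calibrated) * pixel_size
    arc = np.concatenate([[0.0], np.cumsum(steps[:-1])])
    return path, arc, float(steps.sum())
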