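"""Wound-boundary tracing and perimeter measurement.

Two tracers are provided.  The default traces the 0.5 iso-level of the
zero-padded wound mask with marching squares (sub-pixel vertices via linear
interpolation); zero-padding guarantees a closed contour even when the wound
touches the image edge.  To reach sub-pixel accuracy on a *binary* field the
padded mask is first anti-aliased with a small Gaussian (``sigma_c = 1`` px):
iso-contouring the raw indicator places every vertex on a pixel-edge
midpoint, which systematically overestimates smooth boundaries by ~5%,
whereas the regularized field localizes the boundary to a fraction of a
pixel (<1% on rasterized disks, improving with radius).  The alternative
tracer is an 8-direction Moore chain code restricted to whole-pixel turns —
faster and slightly less accurate (staircase bias).

The perimeter is the Euclidean contour length minus the summed length of
segments that lie on the image border, so wounds extending beyond the field
of view are measured by their interior (advancing) front only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "Contour",
    "marching_squares_contour",
    "chain_code_contour",
    "perimeter_excluding_border",
]

#: anti-aliasing scale (px) applied to the padded mask before iso-contouring
PRESMOOTH_SIGMA = 1.0


@dataclass
class Contour:
    """Closed boundary polyline in (row, col) image coordinates.

    Marching-squares vertices are sub-pixel; chain-code vertices are pixel
    centres.  For a nonempty region the first and last vertex coincide.
    """

    vertices: np.ndarray  # (k, 2) float
    closed: bool
    method: str  # "marching_squares" | "chain_code"

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0

    @property
    def length(self) -> float:
        """Total Euclidean length of the polyline."""
        if len(self.vertices) < 2:
            return 0.0
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _longest_contour(field: np.ndarray, level: float = 0.5) -> np.ndarray | None:
    # fully_connected="low" keeps the above-level (wound) phase 4-connected,
    # matching the Von Neumann component labelling
    cs = measure.find_contours(field, level, fully_connected="low")
    best, best_len = None, 0.0
    for c in cs:
        d = np.diff(c, axis=0)
        ln = float(np.hypot(d[:, 0], d[:, 1]).sum())
        if ln > best_len:
            best, best_len = c, ln
    return best


def marching_squares_contour(mask: np.ndarray, presmooth_sigma: float = PRESMOOTH_SIGMA) -> Contour:
    """Trace the region boundary at sub-pixel resolution.

    The mask is zero-padded, anti-aliased at ``presmooth_sigma`` and the 0.5
    level set extracted with marching squares.  Regions too thin to survive
    anti-aliasing (e.g. a single pixel) fall back to the raw binary field,
    whose 0.5 contour is the pixel-edge midpoint polygon.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return Contour(np.empty((0, 2)), closed=False, method="marching_squares")
    pad = max(1, int(math.ceil(4.0 * presmooth_sigma)))
    padded = np.pad(mask, pad).astype(float)
    if presmooth_sigma > 0:
        field = ndimage.gaussian_filter(padded, presmooth_sigma, mode="constant")
    else:
        field = padded
    contour = _longest_contour(field)
    if contour is None:
        contour = _longest_contour(padded)
    if contour is None:  # pragma: no cover - a nonempty padded mask always has one
        return Contour(np.empty((0, 2)), closed=False, method="marching_squares")
    contour = contour - pad
    closed = bool(np.allclose(contour[0], contour[-1]))
    return Contour(contour, closed=closed, method="marching_squares")


# clockwise Moore neighbourhood starting North
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def chain_code_contour(mask: np.ndarray) -> Contour:
    """Moore boundary tracing with 8-direction moves at whole pixels.

    Length = (#axial moves) + sqrt(2) * (#diagonal moves).  Terminates by
    Jacob's criterion (re-entering the start pixel from the start direction).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return Contour(np.empty((0, 2)), closed=False, method="chain_code")
    rows, cols = np.nonzero(mask)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    h, w = mask.shape

    def at(p: tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    verts = [start]
    if not any(at((start[0] + dr, start[1] + dc)) for dr, dc in _MOORE):
        return Contour(np.array([start, start], dtype=float), closed=True, method="chain_code")

    # backtrack starts just outside the region, west of the topmost pixel
    cur = start
    back_dir = 6  # index of the neighbour we came from (West)
    first_move = None
    max_steps = 4 * (mask.sum() + 4)
    for _ in range(int(max_steps)):
        # scan clockwise from the neighbour after the backtrack position
        found = None
        for k in range(1, 9):
            d = (back_dir + k) % 8
            nxt = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if at(nxt):
                found = (d, nxt)
                break
        assert found is not None
        d, nxt = found
        if first_move is None:
            first_move = d
        elif cur == start and d == first_move:
            break
        verts.append(nxt)
        # new backtrack: the previous pixel, seen from the new current pixel
        back_dir = (d + 4) % 8
        cur = nxt
    else:  # pragma: no cover - tracing always terminates on finite masks
        raise RuntimeError("chain-code tracing failed to terminate")
    # drop the overshoot move that re-entered the start
    if len(verts) > 1 and verts[-1] != start:
        verts.append(start)
    arr = np.asarray(verts, dtype=float)
    return Contour(arr, closed=True, method="chain_code")


def _border_lines(image_shape: tuple[int, int], method: str) -> tuple[float, float, float, float]:
    h, w = image_shape
    if method == "chain_code":
        # chain-code vertices are pixel centres; border pixels sit at 0 / dim-1
        return 0.0, float(h - 1), 0.0, float(w - 1)
    # marching-squares contours of a flush region run along the outer pixel
    # edge, half a pixel outside the outermost pixel centres
    return -0.5, h - 0.5, -0.5, w - 0.5


def perimeter_excluding_border(
    contour: Contour,
    image_shape: tuple[int, int],
    correction: str = "geometric",
    tol: float = 1e-6,
) -> float:
    """Wound perimeter: contour length minus the border-coincident part.

    ``correction="geometric"`` (default) subtracts the Euclidean length of
    every segment whose two endpoints lie on the same image-border line,
    keeping one consistent geometric rule for both tracers.
    ``correction="pixel-count"`` instead subtracts one unit of length per
    border-touching contour vertex (the literal pixel-sum reading).
    """
    if contour.is_empty:
        return 0.0
    v = contour.vertices
    top, bottom, left, right = _border_lines(image_shape, contour.method)
    on = np.stack(
        [
            np.abs(v[:, 0] - top) <= tol,
            np.abs(v[:, 0] - bottom) <= tol,
            np.abs(v[:, 1] - left) <= tol,
            np.abs(v[:, 1] - right) <= tol,
        ],
        axis=1,
    )
    total = contour.length
    if correction == "pixel-count":
        n_border = int(np.count_nonzero(on[:-1].any(axis=1)))
        return max(total - float(n_border), 0.0)
    if correction != "geometric":
        raise ValueError("correction must be 'geometric' or 'pixel-count'")
    seg = np.hypot(*(np.diff(v, axis=0).T))
    same_line = (on[:-1] & on[1:]).any(axis=1)
    excluded = float(seg[same_line].sum())
    w_phi = total - excluded
    if w_phi <= tol and total > 0:
        import warnings

        warnings.warn("contour lies entirely on the image border; perimeter is 0", stacklevel=2)
        return 0.0
    return w_phi
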