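"""Synthetic wound-image sequences with analytically known ground truth.

Every downstream stage of the pipeline (detection, contour tracing, GP
modelling, velocity estimation) is testable against these fixtures without
any external imaging data.  The central construction is a wound region that
shrinks at a *constant normal-front speed* ``v``: at time ``t`` the wound is
the initial shape eroded inward by the offset distance ``d = v * t`` along
its normal.  For such a front the exact identity ``dA/dt = -v * P(t)`` holds,
so the concerted cell velocity that the pipeline estimates has a closed-form
ground truth.

Erosion is applied to the *analytic* shape before rasterization (never
morphologically to a raster), keeping the area/perimeter oracle closed-form:

* disk radius ``r0``: ``A = pi (r0-d)^2``, ``P = 2 pi (r0-d)``
* rectangle ``w x h``: inner parallel rectangle ``(w-2d) x (h-2d)``
* ellipse semi-axes ``(a, b)``: the inner parallel curve (valid while
  ``d < b^2/a``, the minimum radius of curvature) has ``P = P0 - 2 pi d``
  and ``A = A0 - P0 d + pi d^2`` (Steiner), with ``P0`` from Ramanujan's
  second approximation
* irregular polygon: high-resolution polygon erosion via Shapely's negative
  buffer; area/length measured on the offset polygon

Cell texture, proliferation and realistic PSFs are deliberately out of scope;
``generate_textured_sequence`` only adds i.i.d. speckle so that the Scharr
gradient path has something to work on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon
from skimage import draw

from .io import FrameSequence

__all__ = [
    "SyntheticWoundSpec",
    "generate_sequence",
    "generate_open_boundary_sequence",
    "generate_textured_sequence",
    "generate_study",
    "write_sequence",
    "ramanujan_perimeter",
]

SHAPES = ("disk", "ellipse", "rectangle", "polygon")

#: default vertex template for the irregular-polygon shape (unit scale,
#: centred on the origin); an asymmetric convex-ish blob
_POLYGON_TEMPLATE = np.array(
    [
        (1.00, 0.00),
        (0.55, 0.72),
        (-0.15, 0.95),
        (-0.80, 0.45),
        (-0.95, -0.25),
        (-0.45, -0.85),
        (0.35, -0.75),
        (0.90, -0.35),
    ]
)


@dataclass(frozen=True)
class SyntheticWoundSpec:
    """Parameters of one synthetic shrinking-wound sequence.

    ``size`` is interpreted per shape: ``(r0,)`` for a disk, semi-axes
    ``(a, b)`` for an ellipse (a >= b), full side lengths ``(w, h)`` for a
    rectangle, and a scale factor ``(s,)`` applied to the built-in polygon
    template for ``polygon``.  All lengths in pixels, times in hours,
    intensities in raw grayscale units (16-bit range).
    """

    shape: str = "disk"
    size: tuple = (100.0,)
    velocity: float = 5.0  # inward normal-front speed, px/h
    dt: float = 1.0  # frame interval, h
    n_frames: int = 16
    image_shape: tuple = (512, 512)
    cell_level: float = 10000.0
    wound_level: float = 500.0
    noise_sd: float = 100.0  # i.i.d. additive Gaussian, clipped to [0, 65535]
    n_artifacts: int = 0  # drifting bright blobs inside the wound
    artifact_radius: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not self.wound_level < self.cell_level:
            raise ValueError("wound intensity must be below cell intensity")
        if self.shape == "ellipse":
            a, b = self.size
            if not a >= b > 0:
                raise ValueError("ellipse size must be semi-axes (a, b) with a >= b > 0")
            d_max = self.velocity * self.times[-1]
            if d_max >= b * b / a:
                raise ValueError(
                    "ellipse erodes past its minimum curvature radius "
                    f"(d_max={d_max:.1f} >= b^2/a={b * b / a:.1f}); "
                    "shorten the sequence or slow the front"
                )
        margin = self._margin()
        if margin < 8:
            raise ValueError(f"shape leaves only {margin:.0f} px of cell margin")

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in hours: the i-th frame is taken at (i+1)*dt."""
        return (np.arange(self.n_frames) + 1) * self.dt

    def _extent(self) -> tuple[float, float]:
        """Half-extent of the initial shape along (rows, cols)."""
        if self.shape == "disk":
            return self.size[0], self.size[0]
        if self.shape == "ellipse":
            a, b = self.size
            return b, a
        if self.shape == "rectangle":
            w, h = self.size
            return h / 2, w / 2
        s = self.size[0]
        verts = _POLYGON_TEMPLATE * s
        return np.abs(verts[:, 1]).max(), np.abs(verts[:, 0]).max()

    def _margin(self) -> float:
        hr, hc = self._extent()
        return min(self.image_shape[0] / 2 - hr, self.image_shape[1] / 2 - hc)


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ellipse perimeter by Ramanujan's second approximation (semi-axes a, b)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _polygon_at(spec: SyntheticWoundSpec, d: float) -> Polygon | None:
    """Shapely polygon of the eroded irregular shape, or None once vanished."""
    s = spec.size[0]
    poly = Polygon(_POLYGON_TEMPLATE * s)
    if d > 0:
        poly = poly.buffer(-d, quad_segs=32)
    if poly.is_empty:
        return None
    if isinstance(poly, MultiPolygon):
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def analytic_truth(spec: SyntheticWoundSpec, d: float) -> tuple[float, float]:
    """(area, perimeter) of the shape eroded inward by offset distance ``d``.

    Returns (0, 0) once the shape has vanished.
    """
    if spec.shape == "disk":
        r = spec.size[0] - d
        if r <= 0:
            return 0.0, 0.0
        return math.pi * r * r, 2 * math.pi * r
    if spec.shape == "ellipse":
        a, b = spec.size
        if d >= b:
            return 0.0, 0.0
        p0 = ramanujan_perimeter(a, b)
        return math.pi * a * b - p0 * d + math.pi * d * d, p0 - 2 * math.pi * d
    if spec.shape == "rectangle":
        w, h = spec.size
        if d >= min(w, h) / 2:
            return 0.0, 0.0
        return (w - 2 * d) * (h - 2 * d), 2 * (w - 2 * d) + 2 * (h - 2 * d)
    poly = _polygon_at(spec, d)
    if poly is None:
        return 0.0, 0.0
    return poly.area, poly.length


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _rasterize(spec: SyntheticWoundSpec, d: float) -> np.ndarray:
    """Boolean wound mask: pixels whose centre lies inside the eroded shape."""
    h, w = spec.image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    mask = np.zeros(spec.image_shape, bool)
    if spec.shape == "disk":
        r = spec.size[0] - d
        if r > 0:
            rr, cc = draw.disk((cy, cx), r, shape=spec.image_shape)
            mask[rr, cc] = True
        return mask
    if spec.shape == "rectangle":
        wid, hei = spec.size
        wi, hi = wid - 2 * d, hei - 2 * d
        if wi > 0 and hi > 0:
            rows = np.arange(h)
            cols = np.arange(w)
            rsel = np.abs(rows - cy) <= hi / 2
            csel = np.abs(cols - cx) <= wi / 2
            mask[np.ix_(rsel, csel)] = True
        return mask
    if spec.shape == "ellipse":
        a, b = spec.size
        if d >= b:
            return mask
        theta = np.linspace(0.0, 2 * np.pi, 1441)
        nx, ny = b * np.cos(theta), a * np.sin(theta)
        norm = np.hypot(nx, ny)
        x = a * np.cos(theta) - d * nx / norm
        y = b * np.sin(theta) - d * ny / norm
        rr, cc = draw.polygon(cy + y, cx + x, shape=spec.image_shape)
        mask[rr, cc] = True
        return mask
    poly = _polygon_at(spec, d)
    if poly is not None:
        x, y = poly.exterior.coords.xy
        rr, cc = draw.polygon(cy + np.asarray(y), cx + np.asarray(x), shape=spec.image_shape)
        mask[rr, cc] = True
    return mask


def _artifact_tracks(spec: SyntheticWoundSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded random-walk tracks of drifting bright blobs, kept strictly
    inside the wound at every frame (so the simply-connected fill removes
    them).  Shape (n_artifacts, n_frames, 2) in (row, col)."""
    if spec.n_artifacts == 0:
        return np.empty((0, spec.n_frames, 2))
    h, w = spec.image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    d_last = spec.velocity * spec.times[-1]
    clearance = spec.artifact_radius + 3.0
    if spec.shape == "polygon":
        safe = _polygon_at(spec, d_last + clearance)
    elif spec.shape == "disk":
        safe = Point(0, 0).buffer(max(spec.size[0] - d_last - clearance, 0.1))
    elif spec.shape == "ellipse":
        a, b = spec.size
        aa = max(a - d_last - clearance, 0.1)
        bb = max(b - d_last - clearance, 0.1)
        th = np.linspace(0, 2 * np.pi, 181)
        safe = Polygon(np.c_[aa * np.cos(th), bb * np.sin(th)])
    else:
        wid, hei = spec.size
        wi = max(wid - 2 * d_last - 2 * clearance, 0.2)
        hi = max(hei - 2 * d_last - 2 * clearance, 0.2)
        safe = Polygon([(-wi / 2, -hi / 2), (wi / 2, -hi / 2), (wi / 2, hi / 2), (-wi / 2, hi / 2)])
    if safe is None or safe.is_empty:
        raise ValueError("wound shrinks too far to host drifting-cell artifacts")
    minx, miny, maxx, maxy = safe.bounds
    tracks = np.empty((spec.n_artifacts, spec.n_frames, 2))
    for k in range(spec.n_artifacts):
        while True:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if safe.contains(Point(x, y)):
                break
        for i in range(spec.n_frames):
            step = rng.normal(0.0, 1.0, size=2)
            if safe.contains(Point(x + step[0], y + step[1])):
                x, y = x + step[0], y + step[1]
            tracks[k, i] = (cy + y, cx + x)
    return tracks


# ---------------------------------------------------------------------------
# sequence generators
# ---------------------------------------------------------------------------


def _assemble(
    spec: SyntheticWoundSpec,
    masks: list[np.ndarray],
    truth_rows: list[tuple[float, float]],
    rng: np.random.Generator,
    tracks: np.ndarray | None = None,
) -> tuple[FrameSequence, pd.DataFrame]:
    frames = []
    for i, mask in enumerate(masks):
        img = np.full(spec.image_shape, spec.cell_level, dtype=np.float64)
        img[mask] = spec.wound_level
        if tracks is not None:
            for k in range(tracks.shape[0]):
                rr, cc = draw.disk(tuple(tracks[k, i]), spec.artifact_radius, shape=spec.image_shape)
                img[rr, cc] = spec.cell_level
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=spec.image_shape)
        frames.append(np.clip(img, 0.0, 65535.0))
    truth = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "time_h": spec.times,
            "area_px2": [a for a, _ in truth_rows],
            "perimeter_px": [p for _, p in truth_rows],
            "v_true": spec.velocity,
        }
    )
    truth["closed"] = truth["area_px2"] <= 0.0
    return FrameSequence(frames=frames, times=spec.times, pixel_scale=1.0), truth


def generate_sequence(spec: SyntheticWoundSpec) -> tuple[FrameSequence, pd.DataFrame]:
    """Render one shrinking-wound sequence plus its analytic ground truth.

    Returns ``(sequence, truth)`` where ``truth`` has columns
    ``frame, time_h, area_px2, perimeter_px, v_true, closed``.  Frames after
    the shape has vanished are pure cell monolayer and flagged closed in the
    truth table.  The same seed yields bit-identical frames.
    """
    rng = np.random.default_rng(spec.seed)
    tracks = _artifact_tracks(spec, rng) if spec.n_artifacts else None
    masks, rows = [], []
    for t in spec.times:
        d = spec.velocity * t
        masks.append(_rasterize(spec, d))
        rows.append(analytic_truth(spec, d))
    return _assemble(spec, masks, rows, rng, tracks)


def generate_open_boundary_sequence(spec: SyntheticWoundSpec) -> tuple[FrameSequence, pd.DataFrame]:
    """Sequence whose wound is flush with the bottom image edge.

    Exercises the image-border exclusion term of the perimeter: the truth
    perimeter is the *interior* boundary only (e.g. the semicircular arc
    ``pi*r`` for a half-disk whose diameter lies on the edge, or the three
    free sides ``w + 2h`` of a flush rectangle).
    """
    if spec.shape not in ("disk", "rectangle"):
        raise ValueError("open-boundary fixtures support disk and rectangle shapes")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    cx = (w - 1) / 2.0
    masks, rows = [], []
    for t in spec.times:
        d = spec.velocity * t
        mask = np.zeros(spec.image_shape, bool)
        if spec.shape == "disk":
            r = spec.size[0] - d
            if r > 0:
                # centre on the outer pixel edge of the last row
                rr, cc = draw.disk((h - 0.5, cx), r, shape=spec.image_shape)
                mask[rr, cc] = True
                rows.append((math.pi * r * r / 2.0, math.pi * r))
            else:
                rows.append((0.0, 0.0))
        else:
            wid, hei = spec.size
            wi, hi = wid - 2 * d, hei - d  # bottom side does not advance
            if wi > 0 and hi > 0:
                cols = np.abs(np.arange(w) - cx) <= wi / 2
                rsel = np.arange(h) >= h - hi - 0.5
                mask[np.ix_(rsel, cols)] = True
                rows.append((wi * hi, wi + 2 * hi))
            else:
                rows.append((0.0, 0.0))
        masks.append(mask)
    return _assemble(spec, masks, rows, rng)


def generate_textured_sequence(
    spec: SyntheticWoundSpec, texture_sd: float = 6000.0
) -> tuple[FrameSequence, pd.DataFrame]:
    """Phase-contrast-like variant: cells and wound share the same *mean*
    intensity, but the cell region carries strong pixel-to-pixel speckle while
    the wound is flat.  Raw intensity thresholding cannot separate the two;
    a gradient-magnitude transform (Scharr) can.
    """
    rng = np.random.default_rng(spec.seed)
    masks, rows = [], []
    for t in spec.times:
        d = spec.velocity * t
        masks.append(_rasterize(spec, d))
        rows.append(analytic_truth(spec, d))
    base = 0.5 * (spec.cell_level + spec.wound_level)
    frames = []
    for mask in masks:
        img = np.full(spec.image_shape, base, dtype=np.float64)
        tex = rng.normal(0.0, texture_sd, size=spec.image_shape)
        img[~mask] += tex[~mask]
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=spec.image_shape)
        frames.append(np.clip(img, 0.0, 65535.0))
    truth = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "time_h": spec.times,
            "area_px2": [a for a, _ in rows],
            "perimeter_px": [p for _, p in rows],
            "v_true": spec.velocity,
        }
    )
    truth["closed"] = truth["area_px2"] <= 0.0
    return FrameSequence(frames=frames, times=spec.times, pixel_scale=1.0), truth


# ---------------------------------------------------------------------------
# multi-condition study fixture
# ---------------------------------------------------------------------------


def _replicate_specs(
    v_mean: float,
    rel_sd: float,
    n_replicates: int,
    rng: np.random.Generator,
    image_shape: tuple,
    n_frames: int,
    dt: float,
) -> Iterator[SyntheticWoundSpec]:
    """Replicates with heterogeneous wound geometry, emulating the shape
    variability of real scratch/exclusion wounds across wells.  The ellipse
    is omitted here because its closed-form erosion window is too short for
    study-length sequences; disks, rectangles and irregular polygons span a
    wide perimeter range, which is what inflates the area-slope spread."""
    shapes = ["disk", "rectangle", "polygon"]
    for i in range(n_replicates):
        shape = shapes[i % len(shapes)]
        v = v_mean * float(np.exp(rng.normal(0.0, rel_sd)))
        if shape == "disk":
            size = (float(rng.uniform(45.0, 70.0)),)
        elif shape == "rectangle":
            size = (float(rng.uniform(130.0, 170.0)), float(rng.uniform(85.0, 110.0)))
        else:
            size = (float(rng.uniform(70.0, 95.0)),)
        yield SyntheticWoundSpec(
            shape=shape,
            size=size,
            velocity=v,
            dt=dt,
            n_frames=n_frames,
            image_shape=image_shape,
            seed=int(rng.integers(0, 2**31 - 1)),
        )


def generate_study(
    conditions: dict[str, float | tuple[float, float]],
    n_replicates: int = 8,
    rel_sd: float = 0.15,
    seed: int = 0,
    image_shape: tuple = (320, 320),
    n_frames: int = 8,
    dt: float = 1.0,
) -> dict[str, list[tuple[FrameSequence, pd.DataFrame]]]:
    """Synthetic multi-condition study.

    ``conditions`` maps labels to a mean front speed, or to a
    ``(speed, rel_sd)`` pair for a condition-specific relative spread
    (e.g. a slow, highly variable no-migration control).  Per condition,
    ``n_replicates`` sequences with heterogeneous wound shapes and a
    per-replicate speed drawn lognormally around the condition mean."""
    rng = np.random.default_rng(seed)
    study: dict[str, list[tuple[FrameSequence, pd.DataFrame]]] = {}
    for label, v in conditions.items():
        v_mean, v_sd = v if isinstance(v, tuple) else (v, rel_sd)
        study[label] = [
            generate_sequence(s)
            for s in _replicate_specs(v_mean, v_sd, n_replicates, rng, image_shape, n_frames, dt)
        ]
    return study


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------


def write_sequence(
    seq: FrameSequence, truth: pd.DataFrame | None, outdir: str | Path, fmt: str = "tif"
) -> Path:
    """Write per-frame 16-bit grayscale images (``frame_{i:03d}.tif``/.png),
    a ``times.csv`` and, if given, the ``ground_truth.csv`` table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("tif", "png"):
        raise ValueError("fmt must be 'tif' or 'png'")
    import imageio.v3 as iio
    import tifffile

    for i, frame in enumerate(seq.frames):
        img = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)
        path = outdir / f"frame_{i:03d}.{fmt}"
        if fmt == "tif":
            tifffile.imwrite(path, img)
        else:
            iio.imwrite(path, img)
    pd.DataFrame({"frame": np.arange(len(seq.frames)), "time_h": seq.times}).to_csv(
        outdir / "times.csv", index=False
    )
    if truth is not None:
        truth.to_csv(outdir / "ground_truth.csv", index=False)
    return outdir
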