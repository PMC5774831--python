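"""Wound detection by confluency-intensity thresholding.

Per frame: Gaussian smoothing at scale ``sigma``, binarization at the
absolute threshold ``beta * I_c`` where the confluency intensity
``I_c = sum(p^2) / sum(p)`` is the intensity-weighted mean pixel intensity
(dominated by the bright cell phase, hence robust to how much of the image
the dark wound occupies), selection of the largest 4-connected (Von Neumann)
below-threshold component — spatially gated to a radius ``r`` around the
reference point after the first two frames — and hole filling so the region
is simply connected (bright drifting cells inside the wound do not bite
pieces out of it).  Area is the pixel count of the filled region; the
perimeter comes from the contour tracers.

Detection uncertainty is estimated by replicating the whole detection at
``n_thresholds`` values evenly spaced in ``beta ± delta_beta`` and taking the
across-replicate mean and variance of area and perimeter, which mimics the
inherent fuzziness of the wound boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .contour import Contour, chain_code_contour, marching_squares_contour, perimeter_excluding_border
from .io import gaussian_smooth

__all__ = [
    "DetectionParams",
    "WoundRegion",
    "WoundMeasurement",
    "confluency_intensity",
    "binarize",
    "select_wound_region",
    "reference_point",
    "wound_area",
    "detect_with_uncertainty",
    "closure_filter",
]

#: 4-connected (Von Neumann) labelling structure
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class DetectionParams:
    """Detection settings.

    Defaults are the fluorescent high-content-screening settings of the
    original assay (smoothing ``sigma = 18`` px at 1.3 um/px, relative
    threshold ``beta = 0.3 ± 0.08``, gating radius ``r = 100`` px, closure at
    5 permille of the image area).  ``sigma`` encodes the length scale of
    cell texture to suppress; the texture-free synthetic fixtures need a much
    smaller scale (see :meth:`for_synthetic`).
    """

    sigma: float = 18.0
    beta: float = 0.3
    delta_beta: float = 0.08
    n_thresholds: int = 5
    radius: float = 100.0
    closure_fraction: float = 0.005
    ic_on_smoothed: bool = True  # compute I_c on the smoothed image
    perimeter_method: str = "marching_squares"
    border_correction: str = "geometric"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 < self.beta - self.delta_beta and self.beta + self.delta_beta < 1):
            raise ValueError("need 0 < beta - delta_beta and beta + delta_beta < 1")
        if self.n_thresholds < 1 or self.n_thresholds % 2 == 0:
            raise ValueError("n_thresholds must be an odd count >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not 0 < self.closure_fraction < 1:
            raise ValueError("closure_fraction must lie in ]0, 1[")
        if self.perimeter_method not in ("marching_squares", "chain_code"):
            raise ValueError("perimeter_method must be 'marching_squares' or 'chain_code'")

    @property
    def thresholds(self) -> np.ndarray:
        """Replicate beta values, evenly spaced and centred on beta."""
        if self.n_thresholds == 1 or self.delta_beta == 0:
            return np.full(self.n_thresholds, self.beta)
        return np.linspace(self.beta - self.delta_beta, self.beta + self.delta_beta, self.n_thresholds)

    @classmethod
    def for_synthetic(cls, **overrides) -> "DetectionParams":
        """Settings matched to the sharp-edged, texture-free synthetic
        fixtures: minimal smoothing and a threshold halfway between wound and
        cell level, which puts the detected boundary on the true edge."""
        defaults = dict(sigma=2.0, beta=0.5, delta_beta=0.08)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class WoundRegion:
    """Selected wound component after hole filling (simply connected)."""

    mask: np.ndarray  # boolean, 4-connected
    centroid: tuple[float, float] | None  # (row, col) centre of mass
    touches_border: bool = False

    @property
    def is_empty(self) -> bool:
        return self.centroid is None

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class WoundMeasurement:
    """Per-frame area/perimeter with detection variances."""

    time: float
    area: float  # px^2, mean over threshold replicates
    area_var: float
    perimeter: float  # px
    perimeter_var: float
    closed: bool = False
    imputed: bool = False
    centroid: tuple[float, float] | None = None
    touches_border: bool = False
    n_found: int = 0  # replicates in which a wound was detected
    contour: Contour | None = None  # traced at the central threshold


def confluency_intensity(frame: np.ndarray) -> float:
    """Intensity-weighted mean intensity ``I_c = sum(p_i^2) / sum(p_i)``."""
    p = np.asarray(frame, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("confluency intensity undefined on an all-zero frame")
    return float(np.square(p).sum() / total)


def binarize(frame: np.ndarray, beta: float, i_c: float) -> np.ndarray:
    """Candidate wound mask: pixels strictly below the absolute threshold
    ``beta * I_c`` (ties go to the cell phase)."""
    if not 0 < beta < 1:
        raise ValueError("beta must lie in ]0, 1[")
    return np.asarray(frame, dtype=float) < beta * i_c


def select_wound_region(
    mask: np.ndarray,
    reference: tuple[float, float] | None = None,
    radius: float | None = None,
) -> WoundRegion:
    """Largest 4-connected below-threshold component, gated and filled.

    When a reference point is given, components whose centroid lies farther
    than ``radius`` from it are discarded (rejects dark corners far from the
    wound).  The surviving largest component has its interior holes filled so
    the returned region is simply connected.  An empty result is returned
    when no component survives.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_4)
    if n == 0:
        return WoundRegion(np.zeros_like(mask), None)
    idx = np.arange(1, n + 1)
    if reference is not None:
        if radius is None:
            raise ValueError("gating radius required with a reference point")
        centroids = np.asarray(ndimage.center_of_mass(mask, labels, idx))
        dist = np.hypot(centroids[:, 0] - reference[0], centroids[:, 1] - reference[1])
        idx = idx[dist <= radius]
        if idx.size == 0:
            return WoundRegion(np.zeros_like(mask), None)
    sizes = ndimage.sum_labels(mask, labels, idx)
    winner = int(idx[np.argmax(sizes)])
    region = labels == winner
    region = ndimage.binary_fill_holes(region, structure=_STRUCTURE_4)
    com = ndimage.center_of_mass(region)
    touches = bool(
        region[0, :].any() or region[-1, :].any() or region[:, 0].any() or region[:, -1].any()
    )
    return WoundRegion(region, (float(com[0]), float(com[1])), touches_border=touches)


def reference_point(
    c1: tuple[float, float] | None, c2: tuple[float, float] | None
) -> tuple[float, float]:
    """Midpoint of the wound centres of mass at the first two time points.

    If the wound was only detected in one of the two frames, that single
    centre is used; if in neither, the sequence cannot be gated.
    """
    if c1 is None and c2 is None:
        raise ValueError("wound not detected in either of the first two frames")
    if c1 is None:
        return c2  # type: ignore[return-value]
    if c2 is None:
        return c1
    return ((c1[0] + c2[0]) / 2.0, (c1[1] + c2[1]) / 2.0)


def wound_area(region: WoundRegion) -> float:
    """Pixel count of the (filled) wound region, in px^2."""
    return float(region.area)


def _trace_perimeter(region: WoundRegion, params: DetectionParams, image_shape) -> tuple[float, Contour]:
    if params.perimeter_method == "chain_code":
        contour = chain_code_contour(region.mask)
    else:
        contour = marching_squares_contour(region.mask)
    w_phi = perimeter_excluding_border(contour, image_shape, correction=params.border_correction)
    return w_phi, contour


def detect_with_uncertainty(
    frame: np.ndarray,
    params: DetectionParams,
    reference: tuple[float, float] | None = None,
    time: float = 0.0,
) -> WoundMeasurement:
    """Full single-frame detection with threshold-replication uncertainty.

    Detection runs at ``n_thresholds`` beta values spanning
    ``beta ± delta_beta``; the measurement is the across-replicate mean and
    (ddof=1) variance of area and perimeter over the replicates in which a
    wound was found.  The contour and centroid at the central beta are kept
    for gating and visualization.  A frame with no wound at any threshold is
    flagged closed with zero area.
    """
    smoothed = gaussian_smooth(frame, params.sigma)
    i_c = confluency_intensity(smoothed if params.ic_on_smoothed else frame)
    areas, perims = [], []
    central = params.thresholds[len(params.thresholds) // 2]
    centroid, contour, touches = None, None, False
    for beta in params.thresholds:
        mask = binarize(smoothed, beta, i_c)
        region = select_wound_region(mask, reference, params.radius)
        if region.is_empty:
            continue
        w_phi, cont = _trace_perimeter(region, params, frame.shape)
        areas.append(wound_area(region))
        perims.append(w_phi)
        if beta == central:
            centroid, contour, touches = region.centroid, cont, region.touches_border
    if not areas:
        return WoundMeasurement(time, 0.0, 0.0, 0.0, 0.0, closed=True)
    areas_arr = np.asarray(areas)
    perims_arr = np.asarray(perims)
    ddof = 1 if len(areas) > 1 else 0
    return WoundMeasurement(
        time=time,
        area=float(areas_arr.mean()),
        area_var=float(areas_arr.var(ddof=ddof)) if len(areas) > 1 else 0.0,
        perimeter=float(perims_arr.mean()),
        perimeter_var=float(perims_arr.var(ddof=ddof)) if len(perims) > 1 else 0.0,
        centroid=centroid,
        touches_border=touches,
        n_found=len(areas),
        contour=contour,
    )


def closure_filter(
    measurements: Sequence[WoundMeasurement],
    n_pixels: int,
    closure_fraction: float = 0.005,
) -> list[WoundMeasurement]:
    """Mark the wound as closed from the first time point whose area falls
    below ``closure_fraction`` of the image area; that and all later points
    are excluded from model training.  A sequence already closed at the first
    time point cannot be modelled and is rejected.
    """
    threshold = closure_fraction * n_pixels
    out = list(measurements)
    crossed = False
    for i, m in enumerate(out):
        if crossed or m.area < threshold:
            crossed = True
            out[i] = replace(m, closed=True)
    if out and out[0].closed:
        raise ValueError("wound closed at the first time point; nothing to model")
    return out
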