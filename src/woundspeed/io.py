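"""Image-sequence loading and preprocessing.

A :class:`FrameSequence` holds ordered 2-D grayscale frames with acquisition
times.  Detection assumes cell regions are brighter than the wound; frames
from non-fluorescent modalities (phase contrast, bright field) can be mapped
onto that assumption with :func:`scharr_gradient`, since textured cell
regions have high gradient magnitude and the smooth cell-free wound has low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["FrameSequence", "load_sequence", "gaussian_smooth", "scharr_gradient"]

#: Gaussian kernel truncation radius in units of sigma.  At the default
#: smoothing scale the detected wound is insensitive to this choice.
GAUSS_TRUNCATE = 4.0

# 3x3 Scharr derivative stencils (normalized to unit total positive weight)
_SCHARR_Y = np.array([[3.0, 10.0, 3.0], [0.0, 0.0, 0.0], [-3.0, -10.0, -3.0]]) / 16.0
_SCHARR_X = _SCHARR_Y.T


@dataclass
class FrameSequence:
    """Time-lapse sequence of one well/condition replicate.

    frames
        Ordered 2-D float arrays of identical shape; nonnegative intensities
        at native bit depth.
    times
        Acquisition times in hours, strictly increasing.
    pixel_scale
        Physical pixel size in micrometres per pixel (1.0 = report in px).
    """

    frames: list[np.ndarray]
    times: np.ndarray
    pixel_scale: float = 1.0
    paths: list[Path] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times differ in length")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D (shape {f.shape})")
            if f.shape != shape:
                raise ValueError(f"frame {i} has shape {f.shape}, expected {shape}")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def n_pixels(self) -> int:
        h, w = self.image_shape
        return h * w

    def __len__(self) -> int:
        return len(self.frames)


def _to_gray(img: np.ndarray, channel: str) -> np.ndarray:
    if img.ndim == 2:
        return np.asarray(img, dtype=float)
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        rgb = np.asarray(img[..., :3], dtype=float)
        if channel in ("mean", "gray"):
            return rgb.mean(axis=-1)
        idx = {"r": 0, "g": 1, "b": 2}.get(channel)
        if idx is None:
            raise ValueError(f"unknown channel {channel!r}")
        return rgb[..., idx]
    raise ValueError(f"unsupported image dimensionality {img.shape}")


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio
    import tifffile

    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return tifffile.imread(path)
        return iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise OSError(f"could not read image {path}") from exc


def load_sequence(
    source: Sequence[str | Path] | str | Path,
    times: Sequence[float] | None = None,
    interval: float | None = None,
    pixel_scale: float = 1.0,
    channel: str = "mean",
) -> FrameSequence:
    """Load a sequence from per-frame files or a multi-page TIFF stack.

    ``source`` is either a list of image paths or a single path (multi-page
    TIFF, or a directory containing ``frame_*`` images and optionally a
    ``times.csv``).  RGB frames are flattened to grayscale by the unweighted
    channel mean (or a single channel via ``channel``).  When no explicit
    ``times`` are given, times default to ``(index + 1) * interval`` —
    the first image is taken one interval after wounding.  Frames are
    reordered by ascending time.
    """
    paths: list[Path]
    frames: list[np.ndarray]
    if isinstance(source, (str, Path)):
        src = Path(source)
        if src.is_dir():
            paths = sorted(p for p in src.iterdir() if p.stem.startswith("frame_"))
            if not paths:
                raise OSError(f"no frame_* images found in {src}")
            frames = [_to_gray(_read_image(p), channel) for p in paths]
            if times is None:
                tcsv = src / "times.csv"
                if tcsv.exists():
                    import pandas as pd

                    times = pd.read_csv(tcsv)["time_h"].to_numpy()
        else:
            import tifffile

            stack = tifffile.imread(src)
            if stack.ndim == 2:
                raise ValueError("a sequence needs at least 2 frames")
            frames = [_to_gray(f, channel) for f in stack]
            paths = [src] * len(frames)
    else:
        paths = [Path(p) for p in source]
        frames = [_to_gray(_read_image(p), channel) for p in paths]

    n = len(frames)
    if times is None:
        if interval is None:
            raise ValueError("provide explicit times or a frame interval")
        times = (np.arange(n) + 1) * float(interval)
    times = np.asarray(times, dtype=float)
    if len(times) != n:
        raise ValueError(f"{n} frames but {len(times)} times")
    order = np.argsort(times, kind="stable")
    frames = [frames[i] for i in order]
    paths = [paths[i] for i in order] if paths else []
    return FrameSequence(frames=frames, times=times[order], pixel_scale=pixel_scale, paths=paths)


def gaussian_smooth(frame: np.ndarray, sigma: float) -> np.ndarray:
    """2-D Gaussian convolution with reflective boundaries.

    Reflection avoids spurious dark frame borders that zero-padding would
    introduce (which the wound threshold would then misclassify).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndimage.gaussian_filter(
        np.asarray(frame, dtype=float), sigma, mode="reflect", truncate=GAUSS_TRUNCATE
    )


def scharr_gradient(frame: np.ndarray) -> np.ndarray:
    """Gradient magnitude ``sqrt(Gx^2 + Gy^2)`` with the 3x3 Scharr pair.

    Invariant to adding a constant to the input; maps textured (cell) regions
    to high output and flat (wound) regions to low output, which restores the
    detection assumption for non-fluorescent images.
    """
    f = np.asarray(frame, dtype=float)
    gx = ndimage.convolve(f, _SCHARR_X, mode="reflect")
    gy = ndimage.convolve(f, _SCHARR_Y, mode="reflect")
    return np.hypot(gx, gy)
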