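"""Image I/O, color conversions, and per-channel statistics.

All rasters are numpy arrays, row-major, origin at the top-left corner
(``x`` = column, ``y`` = row, 0-based).  RGB images are ``(H, W, 3)``
uint8; grayscale images are ``(H, W)`` uint8.  HSV follows the 8-bit
convention used throughout the pupil pipelines: hue in [0, 180]
(half-degrees), saturation and value in [0, 255].

Rounding everywhere is to the nearest integer with ties away from zero,
applied once at the end of each per-pixel formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

#: Working resolution (width, height) of the pupil pipelines.
DEFAULT_SIZE = (333, 250)

CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (values are >= 0 here)."""
    return np.floor(x + 0.5)


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return img


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected an (H, W) grayscale image, got shape {img.shape}")
    return img


@dataclass(frozen=True)
class MeanMatrix:
    """Grid of 3x3 sliding-window channel means.

    ``values`` has shape ``(H - 2, W - 2)`` for an ``(H, W)`` source image;
    cell ``(i, j)`` is the arithmetic mean of the 3x3 source block whose
    center is source pixel ``(i + 1, j + 1)``.  Values are kept real-valued:
    the component-threshold comparisons downstream operate on reals.
    """

    channel: str
    values: np.ndarray
    source_shape: tuple[int, int]

    @property
    def n_entries(self) -> int:
        return int(self.values.size)


def load_and_resize(path, target: tuple[int, int] = DEFAULT_SIZE) -> np.ndarray:
    """Load an RGB image and resize it to ``target`` = (width, height).

    Images already at the target size pass through unchanged.  Downscaling
    uses area averaging, upscaling bilinear interpolation.

    Raises
    ------
    OSError
        If the file is missing or cannot be decoded; the message names the
        path.
    """
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            w, h = im.size
            tw, th = target
            if (w, h) != (tw, th):
                resample = Image.BOX if (tw <= w and th <= h) else Image.BILINEAR
                im = im.resize((tw, th), resample=resample)
            return np.asarray(im, dtype=np.uint8)
    except FileNotFoundError as exc:
        raise OSError(f"cannot read image file: {path!r} (file not found)") from exc
    except OSError as exc:
        raise OSError(f"cannot decode image file: {path!r}: {exc}") from exc


def resize_rgb(img: np.ndarray, target: tuple[int, int] = DEFAULT_SIZE) -> np.ndarray:
    """Resize an in-memory RGB image to ``target`` = (width, height).

    Same interpolation policy as :func:`load_and_resize`; images already at
    the target size are returned unchanged.
    """
    img = _as_rgb(img)
    h, w = img.shape[:2]
    tw, th = target
    if (w, h) == (tw, th):
        return img
    resample = Image.BOX if (tw <= w and th <= h) else Image.BILINEAR
    im = Image.fromarray(np.ascontiguousarray(img.astype(np.uint8))).resize(
        (tw, th), resample=resample
    )
    return np.asarray(im, dtype=np.uint8)


def enhance_exposure(img: np.ndarray, factor: float = 3.0) -> np.ndarray:
    """Brighten an RGB image by per-pixel multiplication, clipped to [0, 255].

    ``factor`` defaults to 3, the exposure enhancement applied before the
    outdoor (red-channel) analysis.  ``factor=1`` is the identity.
    """
    if factor <= 0:
        raise ValueError(f"exposure factor must be > 0, got {factor}")
    img = _as_rgb(img)
    out = _round_half_up(img.astype(np.float64) * factor)
    return np.clip(out, 0, 255).astype(np.uint8)


def sliding_mean_3x3(img: np.ndarray, channel: str = "red") -> MeanMatrix:
    """3x3 unit-stride window means of one color channel.

    Only fully interior window positions are used, so the output grid is
    ``(H - 2) x (W - 2)``; at the 333x250 working resolution that is
    331 x 248 = 82,088 entries.
    """
    img = _as_rgb(img)
    if channel not in CHANNEL_INDEX:
        raise ValueError(f"unknown channel {channel!r}; expected one of {sorted(CHANNEL_INDEX)}")
    h, w = img.shape[:2]
    if h < 3 or w < 3:
        raise ValueError(f"image must be at least 3x3 for the mean matrix, got {h}x{w}")
    plane = img[:, :, CHANNEL_INDEX[channel]].astype(np.float64)
    windows = np.lib.stride_tricks.sliding_window_view(plane, (3, 3))
    values = windows.mean(axis=(-2, -1))
    return MeanMatrix(channel=channel, values=values, source_shape=(h, w))


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit HSV (hue in [0, 180], S and V in [0, 255]).

    Hue is computed on the degree scale (0-360) from the channel maximum /
    minimum, then halved into [0, 180]; saturation is ``(max - min) / max``
    scaled to [0, 255] (0 where max = 0); value is the channel maximum.
    """
    img = _as_rgb(img).astype(np.float64)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    mx = img.max(axis=-1)
    mn = img.min(axis=-1)
    delta = mx - mn

    hue = np.zeros_like(mx)
    with np.errstate(divide="ignore", invalid="ignore"):
        nonzero = delta > 0
        rmax = nonzero & (mx == r)
        gmax = nonzero & (mx == g) & ~rmax
        bmax = nonzero & (mx == b) & ~rmax & ~gmax
        hue[rmax] = 60.0 * (g[rmax] - b[rmax]) / delta[rmax]
        hue[gmax] = 60.0 * (b[gmax] - r[gmax]) / delta[gmax] + 120.0
        hue[bmax] = 60.0 * (r[bmax] - g[bmax]) / delta[bmax] + 240.0
    hue = np.mod(hue, 360.0)

    sat = np.zeros_like(mx)
    pos = mx > 0
    sat[pos] = delta[pos] / mx[pos] * 255.0

    out = np.stack(
        [
            np.mod(_round_half_up(hue / 2.0), 180.0),
            _round_half_up(sat),
            _round_half_up(mx),
        ],
        axis=-1,
    )
    return np.clip(out, 0, 255).astype(np.uint8)


def grayscale_standard(img: np.ndarray) -> np.ndarray:
    """Luma grayscale: ``0.299 R + 0.587 G + 0.114 B``, rounded and clipped."""
    img = _as_rgb(img).astype(np.float64)
    gray = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    return np.clip(_round_half_up(gray), 0, 255).astype(np.uint8)


def grayscale_blue_weighted(img: np.ndarray) -> np.ndarray:
    """Blue-weighted grayscale: ``0.299 R + (0.587 + 0.114) B`` (no green term).

    This variant, with the green weight reassigned to blue, is the default
    preprocessing grayscale of the Hough baseline.
    """
    img = _as_rgb(img).astype(np.float64)
    gray = 0.299 * img[..., 0] + 0.587 * img[..., 2] + 0.114 * img[..., 2]
    return np.clip(_round_half_up(gray), 0, 255).astype(np.uint8)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Standard 8-bit cumulative-histogram equalization.

    Gray level ``v`` maps to ``round((cdf(v) - cdf_min) / (N - cdf_min) * 255)``
    where ``cdf_min`` is the CDF at the lowest occupied level.  A constant
    image (single occupied level) is returned unchanged.
    """
    img = _as_gray(img)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = hist.cumsum()
    n = cdf[-1]
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if n == cdf_min:  # single gray level
        return img.copy()
    lut = _round_half_up((cdf - cdf_min) / (n - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[img]


def gaussian_blur(img: np.ndarray, kernel: int = 5, sigma: float | None = None) -> np.ndarray:
    """Gaussian blur with an odd ``kernel x kernel`` support and edge replication.

    ``sigma`` defaults to ``0.3 * ((kernel - 1) * 0.5 - 1) + 0.8``, the usual
    kernel-size-derived width; ``kernel=1`` is the identity.
    """
    img = _as_gray(img)
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return img.copy()
    if sigma is None:
        sigma = 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8
    radius = (kernel - 1) // 2
    out = ndimage.gaussian_filter(
        img.astype(np.float64), sigma=sigma, mode="nearest", radius=radius
    )
    return np.clip(_round_half_up(out), 0, 255).astype(np.uint8)
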