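"""Canny + circular-Hough comparison baseline.

The comparison algorithm grayscales a single color channel (default: the
blue-weighted grayscale for full-RGB input), equalizes its histogram,
Gaussian-blurs it, extracts Canny edges, and votes circles with the Hough
transform.  A per-channel sweep of the Canny lower threshold (10..70 in
steps of 5, upper = 2 x lower) records the first parameterization that
yields a detection on each of the six channels (R, G, B, H, S, V).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import feature, transform

from pupilkit import geometry, images

log = logging.getLogger(__name__)

CHANNELS = ("red", "green", "blue", "hue", "saturation", "value")


@dataclass(frozen=True)
class CircleDetection:
    """One detected circle: center, radius, channel and Canny thresholds used."""

    center: tuple[float, float]  # (x, y) pixels
    radius: float
    strength: float  # normalized accumulator vote in [0, 1]
    channel: str = ""
    canny: tuple[float, float] = (0.0, 0.0)  # (lower, upper)


@dataclass
class BaselineConfig:
    """Baseline parameters.

    The accumulator vote fraction required to call a circle a detection
    (``vote_threshold``), the radius search range/step, and the minimum
    separation between reported circles are not pinned down by the method
    description; the defaults here are documented choices.
    """

    channels: tuple[str, ...] = ("hue", "saturation")
    canny_lower: float = 50.0
    canny_upper: float = 150.0
    canny_sigma: float = 1.0
    blur_kernel: int = 5
    radius_range: tuple[int, int] = (10, 120)
    radius_step: int = 4
    vote_threshold: float = 0.35
    min_distance: int | None = None  # default: image height // 2
    target_size: tuple[int, int] = images.DEFAULT_SIZE
    sweep_lowers: tuple[int, ...] = tuple(range(10, 71, 5))


def canny_edges(img: np.ndarray, lower: float = 50.0, upper: float = 150.0,
                sigma: float = 1.0) -> np.ndarray:
    """Canny edge map with hysteresis thresholds on the 8-bit intensity scale."""
    if not 0 <= lower <= upper:
        raise ValueError(f"need 0 <= lower <= upper, got lower={lower}, upper={upper}")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a grayscale image, got shape {img.shape}")
    return feature.canny(
        img.astype(np.uint8), sigma=sigma, low_threshold=lower, high_threshold=upper
    )


def hough_circles(
    img: np.ndarray,
    radius_range: tuple[int, int] = (10, 120),
    *,
    radius_step: int = 1,
    vote_threshold: float = 0.35,
    min_distance: int | None = None,
    max_circles: int = 5,
    edges: np.ndarray | None = None,
    canny_thresholds: tuple[float, float] = (50.0, 150.0),
    canny_sigma: float = 1.0,
) -> list[CircleDetection]:
    """Circular Hough voting on the Canny edge map of a grayscale image.

    Returns detections sorted by normalized vote strength (fraction of the
    circle circumference supported by edges); circles below
    ``vote_threshold`` are discarded, so an empty list is a legal outcome.
    """
    rmin, rmax = radius_range
    if rmin <= 0 or rmax < rmin:
        raise ValueError(f"invalid radius range {radius_range}")
    img = np.asarray(img)
    if edges is None:
        edges = canny_edges(img, *canny_thresholds, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(rmin, rmax + 1, radius_step)
    accum = transform.hough_circle(edges, radii, normalize=True)
    if min_distance is None:
        min_distance = img.shape[0] // 2
    # one candidate per radius, then greedy suppression: a weaker circle is
    # dropped if its center is within min_distance of a kept circle *and*
    # its radius is within min_radius_gap — concentric circles of clearly
    # different radii (iris and pupil) both survive
    min_radius_gap = 5
    cands = []
    for i, r in enumerate(radii):
        flat = int(np.argmax(accum[i]))
        y, x = np.unravel_index(flat, accum[i].shape)
        s = float(accum[i, y, x])
        if s >= vote_threshold:
            cands.append((s, float(x), float(y), float(r)))
    cands.sort(reverse=True)
    detections: list[CircleDetection] = []
    for s, x, y, r in cands:
        if len(detections) >= max_circles:
            break
        suppressed = any(
            np.hypot(x - d.center[0], y - d.center[1]) < min_distance
            and abs(r - d.radius) < min_radius_gap
            for d in detections
        )
        if not suppressed:
            detections.append(
                CircleDetection(center=(x, y), radius=r, strength=s)
            )
    return detections


def _channel_plane(frame: np.ndarray, channel: str) -> np.ndarray:
    """Extract one of the six R/G/B/H/S/V channels as a grayscale plane."""
    if channel in images.CHANNEL_INDEX:
        return frame[:, :, images.CHANNEL_INDEX[channel]]
    hsv = images.rgb_to_hsv(frame)
    try:
        idx = ("hue", "saturation", "value").index(channel)
    except ValueError:
        raise ValueError(
            f"unknown channel {channel!r}; expected one of {CHANNELS}"
        ) from None
    return hsv[:, :, idx]


def _preprocess(plane: np.ndarray, blur_kernel: int) -> np.ndarray:
    return images.gaussian_blur(images.equalize_histogram(plane), blur_kernel)


def channel_threshold_sweep(
    frame: np.ndarray, cfg: BaselineConfig | None = None
) -> dict[str, CircleDetection | None]:
    """Canny lower-threshold sweep on all six channels.

    For each channel the preprocessed plane is scanned with lower
    thresholds 10, 15, ..., 70 (upper = 2 x lower); the first
    parameterization yielding a detection is recorded.  Channels with no
    detection map to ``None``.
    """
    cfg = cfg or BaselineConfig()
    frame = images.resize_rgb(frame, cfg.target_size)
    results: dict[str, CircleDetection | None] = {}
    for channel in CHANNELS:
        prep = _preprocess(_channel_plane(frame, channel), cfg.blur_kernel)
        results[channel] = None
        for lower in cfg.sweep_lowers:
            upper = 2 * lower
            hits = hough_circles(
                prep,
                cfg.radius_range,
                radius_step=cfg.radius_step,
                vote_threshold=cfg.vote_threshold,
                min_distance=cfg.min_distance,
                max_circles=1,
                canny_thresholds=(lower, upper),
                canny_sigma=cfg.canny_sigma,
            )
            if hits:
                best = hits[0]
                results[channel] = CircleDetection(
                    center=best.center,
                    radius=best.radius,
                    strength=best.strength,
                    channel=channel,
                    canny=(float(lower), float(upper)),
                )
                break
    return results


def run_baseline(frames, cfg: BaselineConfig | None = None) -> geometry.DiameterSeries:
    """Per-sequence diameter analysis with the Hough-circle baseline.

    Each frame's configured channels are preprocessed (equalize + blur),
    Canny edges extracted at the configured thresholds, and circles voted;
    the strongest detection across channels gives diameter = 2 x radius.
    Frames with no detection are flagged with diameter 0.  No temporal
    correction is applied (the baseline has none), so ``corrected``
    equals ``raw``.
    """
    cfg = cfg or BaselineConfig()
    for channel in cfg.channels:
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    raw = np.zeros(len(frames))
    flagged = np.zeros(len(frames), dtype=bool)
    for i, frame in enumerate(frames):
        frame = images.resize_rgb(frame, cfg.target_size)
        best: CircleDetection | None = None
        for channel in cfg.channels:
            prep = _preprocess(_channel_plane(frame, channel), cfg.blur_kernel)
            hits = hough_circles(
                prep,
                cfg.radius_range,
                radius_step=cfg.radius_step,
                vote_threshold=cfg.vote_threshold,
                min_distance=cfg.min_distance,
                max_circles=1,
                canny_thresholds=(cfg.canny_lower, cfg.canny_upper),
                canny_sigma=cfg.canny_sigma,
            )
            if hits and (best is None or hits[0].strength > best.strength):
                best = hits[0]
        if best is None:
            raw[i], flagged[i] = 0, True
        else:
            raw[i] = 2.0 * best.radius
    return geometry.DiameterSeries(raw=raw, corrected=raw.copy(), flagged=flagged)
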