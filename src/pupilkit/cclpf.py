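"""Outdoor-sunlight pupil pipeline (red-component low-pass filtering).

Under direct sunlight the iris and pupil of a dark-eyed subject are nearly
the same color, so no global grayscale threshold separates them.  This
pipeline instead works on the red channel's 3x3 sliding-mean matrix after
a 3x exposure enhancement: the pupil is the darkest red region, so the
stretch of means starting at the global minimum (the *dark interval*) is
extracted, flattened with a running-minimum filter, and scanned upward for
the first jump larger than a criterion — the upper limit of the pupil
color band.  The extraction threshold is the mean of the lower limit, the
upper limit, and their midpoint (algebraically the midpoint itself), and
the sub-threshold cells form the pupil mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from pupilkit import geometry, images

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DarkInterval:
    """The darkest stretch of the flattened mean matrix.

    ``values`` are the ``n`` consecutive entries (raster order) starting at
    the first occurrence of the global minimum; ``start`` is that flat
    index.  ``truncated`` is set when fewer than ``n`` entries remained.
    """

    values: np.ndarray
    start: int
    target_length: int
    truncated: bool


@dataclass(frozen=True)
class ComponentThreshold:
    """Lower/upper component limits and the final extraction threshold.

    ``final`` is the mean of ``lower``, ``upper`` and their midpoint, which
    equals ``(lower + upper) / 2``.
    """

    lower: float
    upper: float
    final: float
    jump: float


@dataclass
class CclpfConfig:
    """Outdoor-pipeline parameters (defaults are the published constants)."""

    enhance_factor: float = 3.0
    window_length: int = 5000
    jump: float = 5.0
    sort_interval: bool = True
    opening: tuple[int, int] = geometry.DEFAULT_OPENING
    temporal_tol: float = 10.0
    target_size: tuple[int, int] = images.DEFAULT_SIZE


def running_min_filter(seq) -> np.ndarray:
    """Running-minimum (prefix-minimum) low-pass filter.

    The first element initializes the cutoff; every later value above the
    current cutoff is clamped to it, and every value below lowers it.  The
    output is the prefix minimum: non-increasing, pointwise <= the input.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        raise ValueError("cannot filter an empty sequence")
    return np.minimum.accumulate(seq)


def extract_dark_interval(m: images.MeanMatrix, n: int = 5000) -> DarkInterval:
    """Extract ``n`` entries of the flattened mean matrix from its minimum.

    The matrix is flattened row-major; the window runs forward from the
    first occurrence of the global minimum, truncating (with a warning) at
    the end of the flattened sequence.
    """
    if n < 2:
        raise ValueError(f"window length must be >= 2, got {n}")
    flat = np.asarray(m.values, dtype=float).ravel()
    if flat.size == 0:
        raise ValueError("mean matrix is empty")
    start = int(np.argmin(flat))
    window = flat[start : start + n]
    truncated = window.size < n
    if truncated:
        warnings.warn(
            f"dark interval truncated to {window.size} entries "
            f"(minimum at flat index {start} of {flat.size})",
            stacklevel=2,
        )
    return DarkInterval(values=window, start=start, target_length=n, truncated=truncated)


def smooth_dark_interval(d: DarkInterval) -> np.ndarray:
    """Suffix-minimum smoothing of the dark interval.

    Reverse, prefix-minimum, reverse back: upward noise spikes are clamped
    and the result is non-decreasing from the global minimum, which makes
    the jump scan of the component-threshold decision well defined.
    """
    return running_min_filter(d.values[::-1])[::-1]


def decide_component_threshold(smoothed, jump: float = 5.0) -> ComponentThreshold:
    """Scan a non-decreasing sequence for the pupil color band limits.

    Starting from the lowest value, the first consecutive difference larger
    than ``jump`` marks the transition out of the pupil band: the value
    before the jump is the upper limit.  If no difference qualifies the last
    element is the fallback upper limit.  The final threshold averages the
    lower limit, the upper limit, and their midpoint.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size < 2:
        raise ValueError(f"need at least 2 values to decide a threshold, got {smoothed.size}")
    if jump <= 0:
        raise ValueError(f"jump criterion must be > 0, got {jump}")
    lower = float(smoothed[0])
    diffs = np.diff(smoothed)
    over = np.nonzero(diffs > jump)[0]
    upper = float(smoothed[over[0]]) if over.size else float(smoothed[-1])
    final = (lower + upper + (lower + upper) / 2.0) / 3.0
    return ComponentThreshold(lower=lower, upper=upper, final=final, jump=float(jump))


def cclpf_mask(m: images.MeanMatrix, t: ComponentThreshold) -> np.ndarray:
    """Full-resolution pupil mask from sub-threshold mean-matrix cells.

    Mean cell (i, j) below the final threshold marks image pixel
    (i + 1, j + 1) — the center of its 3x3 window — as foreground.
    """
    h, w = m.source_shape
    mask = np.zeros((h, w), dtype=bool)
    mask[1 : h - 1, 1 : w - 1] = m.values < t.final
    return mask


def analyze_frame(frame: np.ndarray, cfg: CclpfConfig | None = None) -> tuple[int, bool]:
    """Run the outdoor pipeline on one RGB frame; return (diameter, flagged)."""
    cfg = cfg or CclpfConfig()
    frame = images.resize_rgb(frame, cfg.target_size)
    enhanced = images.enhance_exposure(frame, cfg.enhance_factor)
    mean = images.sliding_mean_3x3(enhanced, "red")
    interval = extract_dark_interval(mean, cfg.window_length)
    if cfg.sort_interval:
        # Ascending ordering of the dark interval: the threshold scan then
        # walks the window's full value continuum (pupil shading ramp,
        # boundary blend, iris) instead of only the raster tail's minima,
        # so the jump criterion responds to genuine value gaps.  The
        # suffix-minimum smoothing below is the identity on sorted input.
        interval = DarkInterval(
            values=np.sort(interval.values),
            start=interval.start,
            target_length=interval.target_length,
            truncated=interval.truncated,
        )
    smoothed = smooth_dark_interval(interval)
    threshold = decide_component_threshold(smoothed, cfg.jump)
    mask = cclpf_mask(mean, threshold)
    return geometry.mask_to_diameter(mask, cfg.opening)


def run_cclpf(frames, cfg: CclpfConfig | None = None) -> geometry.DiameterSeries:
    """Per-sequence pupil diameter analysis for outdoor-sunlight frames.

    Each frame runs through exposure enhancement, the red mean matrix,
    dark-interval extraction, running-minimum smoothing, the component
    threshold, masking, opening, and contour measurement; the diameter
    sequence is then temporally corrected with a 10 px tolerance.  A frame
    that fails (no contour survives the opening) yields diameter 0 and is
    flagged, never aborting the sequence.
    """
    cfg = cfg or CclpfConfig()
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    raw = np.zeros(len(frames))
    flagged = np.zeros(len(frames), dtype=bool)
    for i, frame in enumerate(frames):
        try:
            raw[i], flagged[i] = analyze_frame(frame, cfg)
        except Exception:  # noqa: BLE001 - frame failures are recorded, not raised
            log.exception("CCLPF failed on frame %d; recording diameter 0", i)
            raw[i], flagged[i] = 0, True
    corrected, substituted = geometry.temporal_correction(raw, cfg.temporal_tol)
    return geometry.DiameterSeries(raw=raw, corrected=corrected, flagged=flagged | substituted)
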