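"""Indoor-artificial-light pupil pipeline (adaptive saturation thresholding).

Under indoor flash photography the pupil is the unique high-saturation
region of the HSV-converted eye image (the flash reflex renders it a
saturated dark red, while the sclera is near-gray and the iris sits in
between).  The saturation cut separating the pupil is found adaptively:
starting at 255 the cut descends in steps of 5; the per-step fractional
gain of mask pixels (the pixel growth ratio) rises while the sweep eats
into the pupil's saturation cluster and first *declines* once the cluster
is exhausted — that step's cut is the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from pupilkit import geometry, images

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HsvBand:
    """Accepted HSV band: full hue and value ranges, saturation >= ``t``."""

    saturation_cut: int
    hue_range: tuple[int, int] = (0, 180)
    value_range: tuple[int, int] = (0, 255)


@dataclass
class SaturationSweepTrace:
    """Diagnostic record of one adaptive-threshold sweep.

    ``thresholds[n] = 255 - step * n``; ``pixel_counts[n]`` is the mask
    size at that cut; ``growth_ratios[n] = (P_n - P_{n-1}) / S`` for n > 0
    (0 at n = 0).  ``stopped_at`` is the step where the first decline was
    observed, or -1 if the no-decline fallback fired.
    """

    thresholds: list[int] = field(default_factory=list)
    pixel_counts: list[int] = field(default_factory=list)
    growth_ratios: list[float] = field(default_factory=list)
    total_pixels: int = 0
    stopped_at: int = -1

    @property
    def fallback(self) -> bool:
        return self.stopped_at < 0

    def to_frame(self):
        """Trace as a DataFrame (step, threshold, pixel count, growth ratio)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(len(self.thresholds)),
                "threshold": self.thresholds,
                "pixel_count": self.pixel_counts,
                "growth_ratio": self.growth_ratios,
            }
        )


def growth_ratio(p_now: int, p_prev: int, total: int) -> float:
    """Pixel growth ratio ``(P_n - P_{n-1}) / S`` of one sweep step."""
    if total <= 0:
        raise ValueError(f"total pixel count must be > 0, got {total}")
    return (p_now - p_prev) / total


def saturation_mask(hsv: np.ndarray, band: HsvBand) -> np.ndarray:
    """Foreground = pixels inside the band (saturation >= the cut)."""
    hsv = np.asarray(hsv)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    return (
        (s >= band.saturation_cut)
        & (h >= band.hue_range[0])
        & (h <= band.hue_range[1])
        & (v >= band.value_range[0])
        & (v <= band.value_range[1])
    )


def adaptive_saturation_threshold(
    hsv: np.ndarray, step: int = 5
) -> tuple[int, SaturationSweepTrace]:
    """Find the saturation cut at the first decline of the growth ratio.

    The sweep starts at 255 and descends by ``step``; the cut of the first
    step ``n >= 2`` with ``G_n < G_{n-1}`` (strict) is returned.  Because
    the mask is a superlevel set, pixel counts are non-decreasing and every
    ratio is non-negative, so the rule terminates by 0 on any non-degenerate
    image; if no decline occurs the cut of maximal growth is the fallback.
    """
    if step < 1:
        raise ValueError(f"sweep step must be >= 1, got {step}")
    hsv = np.asarray(hsv)
    sat = hsv[..., 1]
    total = sat.size
    trace = SaturationSweepTrace(total_pixels=total)
    # cumulative histogram gives every P_n in one pass
    hist = np.bincount(np.asarray(sat, dtype=np.int64).ravel(), minlength=256)
    count_ge = hist[::-1].cumsum()[::-1]  # count_ge[t] = #pixels with sat >= t

    prev_g = 0.0
    chosen: int | None = None
    for n, t in enumerate(range(255, -1, -step)):
        p = int(count_ge[t])
        g = growth_ratio(p, trace.pixel_counts[-1], total) if n > 0 else 0.0
        trace.thresholds.append(t)
        trace.pixel_counts.append(p)
        trace.growth_ratios.append(g)
        if n >= 2 and g < prev_g and chosen is None:
            trace.stopped_at = n
            chosen = t
            break
        if n > 0:
            prev_g = g
    if chosen is None:
        n_max = int(np.argmax(trace.growth_ratios))
        chosen = trace.thresholds[n_max]
        log.debug("no growth-ratio decline; falling back to max-growth cut %d", chosen)
    return chosen, trace


def prssm_mask(hsv: np.ndarray, t: int) -> np.ndarray:
    """Full-resolution pupil mask: pixels with saturation >= ``t``.

    Drawn on a fresh blank canvas; ``t = 256`` is the empty-band sentinel.
    """
    hsv = np.asarray(hsv)
    mask = np.zeros(hsv.shape[:2], dtype=bool)
    if t <= 255:
        mask |= hsv[..., 1] >= t
    return mask


@dataclass
class PrssmConfig:
    """Indoor-pipeline parameters (defaults are the published constants)."""

    sweep_step: int = 5
    opening: tuple[int, int] = geometry.DEFAULT_OPENING
    temporal_tol: float = 5.0
    target_size: tuple[int, int] = images.DEFAULT_SIZE


def analyze_frame(frame: np.ndarray, cfg: PrssmConfig | None = None) -> tuple[int, bool]:
    """Run the indoor pipeline on one RGB frame; return (diameter, flagged)."""
    cfg = cfg or PrssmConfig()
    frame = images.resize_rgb(frame, cfg.target_size)
    hsv = images.rgb_to_hsv(frame)
    t, _ = adaptive_saturation_threshold(hsv, cfg.sweep_step)
    mask = prssm_mask(hsv, t)
    return geometry.mask_to_diameter(mask, cfg.opening)


def run_prssm(frames, cfg: PrssmConfig | None = None) -> geometry.DiameterSeries:
    """Per-sequence pupil diameter analysis for indoor frames.

    Each frame runs through HSV conversion, the adaptive saturation
    threshold, masking, opening, and contour measurement; the diameter
    sequence is then temporally corrected with a 5 px tolerance (the
    indoor pipeline is the more stable of the two, so its permissible
    frame-to-frame error is tighter).  Failing frames yield diameter 0,
    flagged.
    """
    cfg = cfg or PrssmConfig()
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    raw = np.zeros(len(frames))
    flagged = np.zeros(len(frames), dtype=bool)
    for i, frame in enumerate(frames):
        try:
            raw[i], flagged[i] = analyze_frame(frame, cfg)
        except Exception:  # noqa: BLE001 - frame failures are recorded, not raised
            log.exception("PRSSM failed on frame %d; recording diameter 0", i)
            raw[i], flagged[i] = 0, True
    corrected, substituted = geometry.temporal_correction(raw, cfg.temporal_tol)
    return geometry.DiameterSeries(raw=raw, corrected=corrected, flagged=flagged | substituted)
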