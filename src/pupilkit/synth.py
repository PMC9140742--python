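"""Seeded synthetic eye-image generator with ground-truth diameters.

Scenes are a sclera field with concentric iris and pupil disks
(anti-aliased 1-px boundaries), an optional small specular highlight
inside the pupil, and additive Gaussian noise.  Two palettes emulate the
two imaging regimes the pipelines target:

* ``indoor`` — flash photography: the pupil is a saturated dark red (the
  flash reflex), the sclera near-gray, the iris in between, so the pupil
  is the unique highest-saturation region.
* ``outdoor`` — direct sunlight: iris and pupil are both dark with a
  small red-channel gap (pupil darkest), emulating the low iris/pupil
  contrast of dark-eyed subjects in sunlight.

Noise is an additive Gaussian random field with unit-free marginal
standard deviation ``noise_sd`` per channel and spatial correlation
length ``noise_corr`` (pixels).  The default field is smooth: smartphone
camera pipelines denoise aggressively, so the residual variation in real
frames is low-frequency illumination/shading drift rather than white
sensor noise.  ``noise_corr=0`` gives i.i.d. pixel noise.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from pupilkit import images

RGB = tuple[int, int, int]

#: Indoor (flash) palette: pupil saturated red, iris muted brown, sclera near-gray.
INDOOR_SCLERA: RGB = (228, 225, 220)
INDOOR_IRIS: RGB = (110, 90, 72)
INDOOR_PUPIL: RGB = (75, 22, 18)

#: Outdoor (sunlight) palette: dark iris and pupil, small red gap, pupil darkest.
OUTDOOR_SCLERA: RGB = (210, 200, 195)
OUTDOOR_IRIS: RGB = (85, 67, 54)
OUTDOOR_PUPIL: RGB = (64, 48, 40)

HIGHLIGHT_COLOR: RGB = (255, 255, 255)


def _saturation(color: RGB) -> float:
    """8-bit HSV saturation of a single RGB triple."""
    mx, mn = max(color), min(color)
    return 0.0 if mx == 0 else (mx - mn) / mx * 255.0


@dataclass
class EyeSceneParams:
    """Geometry, palette, and noise of one synthetic eye scene."""

    size: tuple[int, int] = images.DEFAULT_SIZE  # (width, height)
    center: tuple[float, float] = (166.0, 125.0)  # (x, y)
    pupil_radius: float = 30.0
    iris_radius: float = 70.0
    mode: str = "indoor"
    sclera: RGB | None = None
    iris: RGB | None = None
    pupil: RGB | None = None
    highlight: bool = True
    highlight_radius: float = 3.0
    highlight_offset: tuple[float, float] = (4.0, -4.0)
    optics_blur: float = 0.0
    noise_sd: float = 5.0
    noise_corr: float = 250.0
    noise_shared: bool = True
    shading_depth: float = 0.35
    shading_power: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("indoor", "outdoor"):
            raise ValueError(f"mode must be 'indoor' or 'outdoor', got {self.mode!r}")
        defaults = (
            (INDOOR_SCLERA, INDOOR_IRIS, INDOOR_PUPIL)
            if self.mode == "indoor"
            else (OUTDOOR_SCLERA, OUTDOOR_IRIS, OUTDOOR_PUPIL)
        )
        if self.sclera is None:
            self.sclera = defaults[0]
        if self.iris is None:
            self.iris = defaults[1]
        if self.pupil is None:
            self.pupil = defaults[2]
        self.validate()

    def validate(self) -> None:
        if not self.pupil_radius < self.iris_radius:
            raise ValueError(
                f"pupil radius ({self.pupil_radius}) must be smaller than "
                f"iris radius ({self.iris_radius})"
            )
        if self.mode == "indoor":
            sp, si, ss = map(_saturation, (self.pupil, self.iris, self.sclera))
            if not (sp > si + 30 and si > ss + 30):
                raise ValueError(
                    "indoor palette must satisfy saturation(pupil) > saturation(iris) "
                    f"> saturation(sclera) with margins >= 30; got pupil={sp:.0f}, "
                    f"iris={si:.0f}, sclera={ss:.0f}"
                )
        else:
            rp, ri, rs = self.pupil[0], self.iris[0], self.sclera[0]
            if not rp < ri < rs:
                raise ValueError(
                    "outdoor palette must satisfy red(pupil) < red(iris) < red(sclera); "
                    f"got pupil={rp}, iris={ri}, sclera={rs}"
                )
            if ri - rp > 25:
                raise ValueError(
                    f"outdoor pupil-iris red gap must be <= 25 (low contrast); got {ri - rp}"
                )


@dataclass
class ConstrictionProfile:
    """Exponential pupil constriction: d(t) = end + (start - end) * exp(-t / tau).

    ``start``/``end`` are diameters in pixels; ``tau`` is the constriction
    time constant in frames (default: a quarter of the sequence length).
    """

    start: float = 90.0
    end: float = 45.0
    tau: float | None = None

    def diameters(self, n: int) -> np.ndarray:
        tau = self.tau if self.tau is not None else max(n / 4.0, 1.0)
        t = np.arange(n)
        return self.end + (self.start - self.end) * np.exp(-t / tau)


@dataclass
class GroundTruthSeries:
    """Per-frame true pupil diameters (pixels) and their provenance."""

    diameters: np.ndarray
    seed: int
    profile: ConstrictionProfile | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self.diameters)),
                "true_diameter_px": self.diameters,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _disk_coverage(xx: np.ndarray, yy: np.ndarray, center: tuple[float, float],
                   radius: float) -> np.ndarray:
    """Per-pixel coverage of an anti-aliased disk (1-px linear boundary ramp)."""
    d = np.hypot(xx - center[0], yy - center[1])
    return np.clip(radius + 0.5 - d, 0.0, 1.0)


def _noise_field(shape: tuple[int, int, int], sd: float, corr: float,
                 rng: np.random.Generator, shared: bool = True) -> np.ndarray:
    """Gaussian random field, marginal sd ``sd`` per channel, correlation ``corr`` px.

    With ``shared=True`` one field is added to all three channels
    (luminance drift, the dominant residual variation in ISP-denoised
    smartphone frames); otherwise each channel gets an independent field.
    """
    n_fields = 1 if shared else shape[2]
    white = rng.standard_normal((shape[0], shape[1], n_fields))
    if corr <= 0:
        fields = white * sd
    else:
        fields = np.empty_like(white)
        for c in range(n_fields):
            f = ndimage.gaussian_filter(white[..., c], sigma=corr, mode="reflect")
            s = f.std()
            fields[..., c] = 0.0 if s == 0 else (f - f.mean()) / s * sd
    if shared:
        fields = np.repeat(fields, shape[2], axis=2)
    return fields


def render_eye(params: EyeSceneParams) -> tuple[np.ndarray, float]:
    """Render one scene; returns ``(rgb_image, true_diameter_px)``.

    Fully determined by ``params`` (including its seed).  The true
    diameter is ``2 * pupil_radius``.
    """
    params.validate()
    w, h = params.size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = params.sclera

    cov_iris = _disk_coverage(xx, yy, params.center, params.iris_radius)[..., None]
    img += cov_iris * (np.asarray(params.iris, dtype=float) - img)
    cov_pupil = _disk_coverage(xx, yy, params.center, params.pupil_radius)[..., None]
    # Radial luminance shading inside the pupil: real pupils image darker at
    # the center than at the rim (off-axis illumination through the cornea).
    # The factor is multiplicative, so HSV saturation is unaffected.
    u = np.clip(
        np.hypot(xx - params.center[0], yy - params.center[1]) / max(params.pupil_radius, 1e-9),
        0.0,
        1.0,
    )
    shade = 1.0 - params.shading_depth * (1.0 - u**params.shading_power)
    pupil_color = np.asarray(params.pupil, dtype=float) * shade[..., None]
    img += cov_pupil * (pupil_color - img)

    if params.highlight and params.highlight_radius > 0:
        hc = (
            params.center[0] + params.highlight_offset[0],
            params.center[1] + params.highlight_offset[1],
        )
        cov_hl = _disk_coverage(xx, yy, hc, params.highlight_radius)[..., None]
        img += cov_hl * (np.asarray(HIGHLIGHT_COLOR, dtype=float) - img)

    if params.optics_blur > 0:
        # point-spread blur of the camera optics, applied to the clean scene
        img = ndimage.gaussian_filter(img, sigma=(params.optics_blur, params.optics_blur, 0))

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        img += _noise_field(
            (h, w, 3), params.noise_sd, params.noise_corr, rng, params.noise_shared
        )

    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, 2.0 * params.pupil_radius


def pupil_mask_from_scene(img: np.ndarray, params: EyeSceneParams) -> np.ndarray:
    """Ground-truth pupil mask from a rendered scene's own colors.

    Classifies pixels by the red channel against the pupil/iris midpoint —
    exact for noiseless scenes (the self-consistency oracle); not intended
    for noisy frames.
    """
    cut = (params.pupil[0] + params.iris[0]) / 2.0
    return img[:, :, 0].astype(float) < cut


def generate_sequence(
    n: int = 80,
    profile: ConstrictionProfile | None = None,
    params: EyeSceneParams | None = None,
    jitter: float = 2.0,
) -> tuple[list[np.ndarray], GroundTruthSeries]:
    """Render an ``n``-frame constriction sequence with ground truth.

    Frame ``t`` is the scene at diameter ``profile.diameters(n)[t]`` with
    the disk center jittered by at most ``jitter`` pixels per axis and a
    fresh noise draw; everything derives deterministically from
    ``params.seed``.
    """
    if n < 1:
        raise ValueError(f"need at least one frame, got n={n}")
    profile = profile or ConstrictionProfile()
    params = params or EyeSceneParams()
    diameters = profile.diameters(n)
    lo, hi = 20.0, 2.0 * (params.iris_radius - 2.0)
    if diameters.min() < lo or diameters.max() > hi:
        raise ValueError(
            f"profile diameters [{diameters.min():.1f}, {diameters.max():.1f}] outside "
            f"the valid range [{lo}, {hi}] for iris radius {params.iris_radius}"
        )
    master = np.random.SeedSequence(params.seed)
    frame_seeds = master.spawn(n)
    rng_jitter = np.random.default_rng(master.spawn(1)[0])
    frames = []
    for t in range(n):
        dx, dy = rng_jitter.uniform(-jitter, jitter, size=2)
        frame_params = replace(
            params,
            center=(params.center[0] + dx, params.center[1] + dy),
            pupil_radius=diameters[t] / 2.0,
            seed=int(frame_seeds[t].generate_state(1)[0] % (2**31)),
        )
        img, _ = render_eye(frame_params)
        frames.append(img)
    return frames, GroundTruthSeries(diameters=diameters, seed=params.seed, profile=profile)


def write_sequence(
    out_dir,
    n: int = 80,
    profile: ConstrictionProfile | None = None,
    params: EyeSceneParams | None = None,
    jitter: float = 2.0,
) -> Path:
    """Generate a sequence and write numbered PNG frames + truth.csv + params.yaml."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = params or EyeSceneParams()
    profile = profile or ConstrictionProfile()
    frames, truth = generate_sequence(n, profile, params, jitter)
    for t, frame in enumerate(frames):
        Image.fromarray(frame).save(out_dir / f"frame_{t:04d}.png")
    truth.to_csv(out_dir / "truth.csv")
    sidecar = {
        "n_frames": n,
        "jitter": jitter,
        "profile": asdict(profile),
        "scene": asdict(params),
    }
    with open(out_dir / "params.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return out_dir
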