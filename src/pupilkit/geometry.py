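"""Shared geometric back half of both pupil pipelines.

Binary-mask cleanup (morphological opening with a solid rectangle),
contour extraction over 8-connected components, bounding-box diameter
measurement, and the rule-of-thumb temporal correction of diameter
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

#: Default structuring-element size for mask cleanup (square, in pixels).
DEFAULT_OPENING = (10, 10)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Contour:
    """Outer boundary of one 8-connected foreground component.

    ``boundary`` is an ordered, closed list of (x, y) pixel coordinates
    traced around the component; ``bbox`` is (min_x, min_y, max_x, max_y)
    inclusive, over the component's pixels; ``area`` is the component's
    pixel count.
    """

    boundary: np.ndarray
    bbox: tuple[int, int, int, int]
    area: int

    @property
    def width(self) -> int:
        return self.bbox[2] - self.bbox[0] + 1

    @property
    def height(self) -> int:
        return self.bbox[3] - self.bbox[1] + 1


@dataclass
class DiameterSeries:
    """Per-frame raw and temporally corrected pupil diameters, in pixels.

    ``flagged[t]`` marks frames where no contour was found (raw 0) or where
    the temporal rule substituted the previous diameter.
    """

    raw: np.ndarray
    corrected: np.ndarray
    flagged: np.ndarray
    frame_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.corrected = np.asarray(self.corrected, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.frame_index is None:
            self.frame_index = np.arange(len(self.raw))
        self.frame_index = np.asarray(self.frame_index, dtype=int)

    def __len__(self) -> int:
        return len(self.raw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_index,
                "raw_px": self.raw,
                "corrected_px": self.corrected,
                "flagged": self.flagged.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DiameterSeries":
        df = pd.read_csv(path)
        return cls(
            raw=df["raw_px"].to_numpy(),
            corrected=df["corrected_px"].to_numpy(),
            flagged=df["flagged"].to_numpy().astype(bool),
            frame_index=df["frame_index"].to_numpy(),
        )


def morphological_opening(mask: np.ndarray, se: tuple[int, int] = DEFAULT_OPENING) -> np.ndarray:
    """Opening (erosion then dilation) with a solid ``se`` rectangle.

    Removes foreground features that cannot contain the structuring
    element — in the pupil pipelines, the specular-highlight speckle.
    The even-sized default 10x10 element is anchored at cell (5, 5).
    """
    mask = np.asarray(mask, dtype=bool)
    sh, sw = se
    if sh < 1 or sw < 1:
        raise ValueError(f"structuring element must be at least 1x1, got {se}")
    structure = np.ones((sh, sw), dtype=bool)
    return ndimage.binary_opening(mask, structure=structure)


def extract_contours(mask: np.ndarray) -> list[Contour]:
    """Outer boundaries of all 8-connected foreground components.

    Hole (inner) boundaries are ignored.  Each contour's bounding box and
    area come from the component's pixels; the ordered boundary is traced
    at the half-level around the component.  Components are returned in
    label order (raster order of first pixel).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    contours: list[Contour] = []
    slices = ndimage.find_objects(labels)
    for lab, sl in zip(range(1, n + 1), slices):
        comp = labels[sl] == lab
        rows, cols = np.nonzero(comp)
        min_y, max_y = sl[0].start + rows.min(), sl[0].start + rows.max()
        min_x, max_x = sl[1].start + cols.min(), sl[1].start + cols.max()
        # trace the outer boundary on a padded, hole-filled crop so inner
        # boundaries never appear
        filled = ndimage.binary_fill_holes(comp)
        padded = np.pad(filled, 1)
        trace = measure.find_contours(padded.astype(float), 0.5)[0]
        # (row, col) in padded crop coords -> (x, y) pixel coords
        ys = np.clip(np.round(trace[:, 0] - 1).astype(int), 0, comp.shape[0] - 1) + sl[0].start
        xs = np.clip(np.round(trace[:, 1] - 1).astype(int), 0, comp.shape[1] - 1) + sl[1].start
        pts = np.column_stack([xs, ys])
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        contours.append(
            Contour(
                boundary=pts[keep],
                bbox=(int(min_x), int(min_y), int(max_x), int(max_y)),
                area=int(comp.sum()),
            )
        )
    return contours


def measure_diameter(contours: list[Contour]) -> tuple[int, bool]:
    """Pupil diameter from a contour list: max bounding-box extent, in pixels.

    The largest-area contour is taken to be the pupil and its diameter is
    ``max(bbox width, bbox height)`` — robust to imperfect (notched or
    partially occluded) pupil outlines.  An empty list yields ``(0, True)``,
    the flagged no-detection sentinel.
    """
    if not contours:
        return 0, True
    best = max(contours, key=lambda c: c.area)
    return max(best.width, best.height), False


def temporal_correction(raw, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Rule-of-thumb correction of a diameter sequence.

    A frame whose diameter differs from the previous *accepted* diameter by
    more than ``tol`` pixels is replaced by that previous diameter (single
    bad frames — lost contours, reflections — cannot move the series).
    Returns ``(corrected, substituted)``.
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be > 0, got {tol}")
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("cannot correct an empty diameter sequence")
    corrected = raw.copy()
    substituted = np.zeros(raw.size, dtype=bool)
    for t in range(1, raw.size):
        if abs(raw[t] - corrected[t - 1]) > tol:
            corrected[t] = corrected[t - 1]
            substituted[t] = True
    return corrected, substituted


def mask_to_diameter(mask: np.ndarray, se: tuple[int, int] = DEFAULT_OPENING) -> tuple[int, bool]:
    """Opening -> contours -> diameter, the shared tail of both pipelines."""
    opened = morphological_opening(mask, se)
    return measure_diameter(extract_contours(opened))
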