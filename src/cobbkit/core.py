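"""Core data containers shared across the pipeline.

Coordinate convention (fixed throughout the package): x grows rightward,
y grows downward, pixel indices are 0-based floats, and the four corners
of a vertebra are always ordered (UL, UR, LL, LR) in the vertebra's own
orientation.  Angles are in degrees; a positive inclination is a clockwise
tilt in image coordinates (right side lower than the left).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

N_VERTEBRAE = 17

#: Anatomical labels for the 17 levels the pipeline assumes visible, T1..L5.
LEVELS = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]

#: Index of T11; curves whose apex is at or above this level are thoracic.
T11_INDEX = 10


class Corner(IntEnum):
    """Corner channel order: upper-left, upper-right, lower-left, lower-right."""

    UL = 0
    UR = 1
    LL = 2
    LR = 3


CORNER_NAMES = ["UL", "UR", "LL", "LR"]


@dataclass
class SpineImage:
    """A gray-scale radiograph plus the metadata the pipeline needs.

    pixels is a 2-D float or integer array (H, W); intensity_range records
    the nominal dynamic range of the source (e.g. (0, 255) for 8-bit PNG),
    posture tags the imaging condition.
    """

    pixels: np.ndarray
    intensity_range: tuple[float, float] = (0.0, 1.0)
    posture: str = "standing"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D gray-scale image, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (H, W)


@dataclass
class ROIBox:
    """Normalized thoracolumbar bounding box: (x1, y1) upper-left, (x2, y2) lower-right."""

    x1: float
    y1: float
    x2: float
    y2: float

    def validate(self) -> "ROIBox":
        if not (0.0 <= self.x1 < self.x2 <= 1.0 and 0.0 <= self.y1 < self.y2 <= 1.0):
            raise ValueError(f"invalid ROI box {self.as_array()}: need 0<=x1<x2<=1, 0<=y1<y2<=1")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)

    @classmethod
    def from_array(cls, a) -> "ROIBox":
        a = np.asarray(a, dtype=float).reshape(4)
        return cls(*a)

    def to_pixels(self, image_shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """Return (x1, y1, x2, y2) in pixel units of an (H, W) image."""
        h, w = image_shape
        return self.x1 * w, self.y1 * h, self.x2 * w, self.y2 * h

    def iou(self, other: "ROIBox") -> float:
        ix1, iy1 = max(self.x1, other.x1), max(self.y1, other.y1)
        ix2, iy2 = min(self.x2, other.x2), min(self.y2, other.y2)
        inter = max(0.0, ix2 - ix1) * max(0.0, iy2 - iy1)
        a = (self.x2 - self.x1) * (self.y2 - self.y1)
        b = (other.x2 - other.x1) * (other.y2 - other.y1)
        return inter / (a + b - inter) if inter > 0 else 0.0


@dataclass
class LandmarkSet:
    """17 vertebrae x 4 corners in image pixel coordinates.

    points: (17, 4, 2) array of (x, y); present: (17, 4) bool flags;
    confidence: (17, 4) scores in [0, 1] (1.0 for ground truth);
    completed: (17, 4) bool, True where a corner was inferred by
    parallelogram completion rather than detected.
    """

    points: np.ndarray
    present: np.ndarray = field(default=None)  # type: ignore[assignment]
    confidence: np.ndarray = field(default=None)  # type: ignore[assignment]
    completed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_VERTEBRAE, 4, 2):
            raise ValueError(f"landmark array must be (17, 4, 2), got {self.points.shape}")
        if self.present is None:
            self.present = np.ones((N_VERTEBRAE, 4), dtype=bool)
        if self.confidence is None:
            self.confidence = np.ones((N_VERTEBRAE, 4), dtype=float)
        if self.completed is None:
            self.completed = np.zeros((N_VERTEBRAE, 4), dtype=bool)
        self.present = np.asarray(self.present, dtype=bool)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.completed = np.asarray(self.completed, dtype=bool)

    @property
    def all_present(self) -> bool:
        return bool(self.present.all())

    def centroids(self) -> np.ndarray:
        """(17, 2) vertebral centroids (mean of the four corners)."""
        return self.points.mean(axis=1)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            self.points.copy(), self.present.copy(), self.confidence.copy(), self.completed.copy()
        )


@dataclass
class Curve:
    """A spinal curve bounded by its two end vertebrae (indices into T1..L5)."""

    upper_end: int
    lower_end: int
    cobb_angle: float
    apex: Optional[int] = None
    region: str = "thoracic"  # or "lumbar"
    rank: str = "unranked"  # major / minor1 / minor2 / unranked
    direction: int = 0  # sign of inclination[upper] - inclination[lower]

    def __post_init__(self) -> None:
        if not self.upper_end < self.lower_end:
            raise ValueError("curve end vertebrae must satisfy upper_end < lower_end")
        if self.cobb_angle < 0:
            raise ValueError("cobb_angle is an unsigned magnitude")

    def key(self) -> tuple:
        return (self.upper_end, self.lower_end, round(self.cobb_angle, 6))


@dataclass
class CurveSet:
    """Detected curves plus the inclination profile they were derived from."""

    curves: list[Curve] = field(default_factory=list)
    inclinations: Optional[np.ndarray] = None

    def ranked(self) -> list[Curve]:
        order = {"major": 0, "minor1": 1, "minor2": 2}
        return sorted(
            (c for c in self.curves if c.rank in order), key=lambda c: order[c.rank]
        )

    def by_rank(self, rank: str) -> Optional[Curve]:
        for c in self.curves:
            if c.rank == rank:
                return c
        return None

    @property
    def major(self) -> Optional[Curve]:
        return self.by_rank("major")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)
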