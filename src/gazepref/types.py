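"""Shared domain types.

Coordinate convention used throughout the package: image x increases
rightward, y increases downward, pixel indices are 0-based.  "Left eye" /
"right eye" are named in image coordinates (left = smaller x), not
anatomically, because the gaze rule operates in image space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class GazeLabel(enum.Enum):
    """Per-frame gaze outcome of the preferential-looking classifier."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"
    CENTER = "CENTER"
    DISTRACTION = "DISTRACTION"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Labels attributable to one of the two stimulus scenes.
LATERAL_LABELS = (GazeLabel.LEFT, GazeLabel.RIGHT)


class Scene(enum.Enum):
    """The two halves of the stimulus screen."""

    SOCIAL = "SOCIAL"
    ABSTRACT = "ABSTRACT"


@dataclass(frozen=True)
class Region:
    """Axis-aligned pixel rectangle (top-left corner + size)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"region must have positive size, got {self.w}x{self.h}")

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    def contains(self, other: "Region") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and other.x2 <= self.x2
            and other.y2 <= self.y2
        )

    def intersects(self, other: "Region") -> bool:
        return not (
            other.x >= self.x2
            or other.x2 <= self.x
            or other.y >= self.y2
            or other.y2 <= self.y
        )

    def iou(self, other: "Region") -> float:
        """Intersection-over-union of two rectangles."""
        ix = max(0, min(self.x2, other.x2) - max(self.x, other.x))
        iy = max(0, min(self.y2, other.y2) - max(self.y, other.y))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union else 0.0

    def crop(self, image: np.ndarray) -> np.ndarray:
        """Extract this region from an image array (row = y, col = x)."""
        return image[self.y : self.y2, self.x : self.x2]

    def mirrored(self, image_width: int) -> "Region":
        """The region after horizontal mirroring of an image of given width."""
        return Region(image_width - self.x2, self.y, self.w, self.h)


@dataclass(frozen=True)
class IrisLocation:
    """Iris circle within an eye-region raster (local pixel coordinates)."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("iris radius must be positive")


def validate_rgb(frame: np.ndarray) -> np.ndarray:
    """Check that ``frame`` is an (H, W, 3) uint8 RGB raster."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB frame, got shape {frame.shape}")
    if frame.dtype != np.uint8:
        raise ValueError(f"expected uint8 frame, got {frame.dtype}")
    return frame
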