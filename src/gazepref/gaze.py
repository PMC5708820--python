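"""Gaze classification from sclera brightness: the core of the pipeline.

For each detected eye the iris is localized as the best-supported dark
circular blob (a circular accumulator over a Prewitt edge map of the
black-enhanced raster).  A horizontal lightness profile is then read through
the iris center, extending beyond the iris radius on both sides, and the
brightest pixel of each sclera flank gives the pair (LR, RR) — left-region
and right-region peak brightness.  Lateral gaze shifts the iris toward one
eye corner, extinguishing the sclera on that side, so the ratio of the two
peaks encodes gaze direction:

    LR / RR <= t          ->  RIGHT  (gaze at the right half of the screen)
    RR / LR <= t          ->  LEFT
    min/max ratio  >  t   ->  CENTER

with the decision threshold t = 0.85 by default.  The three cases partition
all positive (LR, RR) pairs for t < 1; boundary equality is inclusive.  Any
degenerate stage (no iris, empty sclera region, zero brightness) folds into
DISTRACTION with a logged reason, as does a frame whose two eyes disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .detect import DetectionResult
from .enhance import DEFAULT_CONFIG, EnhanceConfig, black_region_enhance, enhanced_lightness
from .types import GazeLabel, IrisLocation, Region, validate_rgb

#: Decision threshold selected by concordance calibration against manual
#: annotation (the shipped default).
DEFAULT_THRESHOLD = 0.85


class NoIrisError(RuntimeError):
    """No circular blob with enough edge support in the eye raster."""


class DegenerateProfileError(RuntimeError):
    """Brightness profile leaves no usable sclera region."""


# 3x3 un-normalized Prewitt kernels; Gx responds to horizontal gradients.
_PREWITT_GX = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]], dtype=float)
_PREWITT_GY = _PREWITT_GX.T


def prewitt_edges(raster: np.ndarray) -> np.ndarray:
    """Prewitt gradient magnitude sqrt(Gx^2 + Gy^2), reflected borders.

    Kernels are the raw 3x3 Prewitt stencils (not normalized by 1/3), so an
    ideal vertical step of height h yields interior magnitude 3h.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2 or min(raster.shape) < 3:
        raise ValueError(f"need a single-channel raster >= 3x3, got {raster.shape}")
    gx = ndimage.convolve(raster, _PREWITT_GX, mode="reflect")
    gy = ndimage.convolve(raster, _PREWITT_GY, mode="reflect")
    return np.hypot(gx, gy)


def _ring_kernel(radius: int, width: float = 0.75) -> np.ndarray:
    r = int(np.ceil(radius + width))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.hypot(xx, yy)
    ring = (np.abs(d - radius) <= width).astype(float)
    return ring / ring.sum()


def locate_iris(
    eye_raster: np.ndarray,
    radius_bounds: tuple[int, int] | None = None,
    min_support: float = 20.0,
) -> IrisLocation:
    """Find the iris circle in a black-enhanced eye raster.

    A circular accumulator scores every (center, radius) by the mean Prewitt
    edge magnitude along the circle; the global maximum wins (ties resolve
    to the smallest radius, then row-major first center — deterministic).
    ``radius_bounds`` defaults to (10%, 40%) of the raster height.  A best
    score below ``min_support`` (mean gradient units) raises
    :class:`NoIrisError`.
    """
    eye_raster = np.asarray(eye_raster, dtype=float)
    if eye_raster.ndim != 2:
        raise ValueError("locate_iris expects a single-channel raster")
    h, w = eye_raster.shape
    if radius_bounds is None:
        radius_bounds = (max(3, round(0.10 * h)), max(4, round(0.40 * h)))
    r_lo, r_hi = radius_bounds
    if r_lo < 1 or r_hi < r_lo:
        raise ValueError(f"bad radius bounds {radius_bounds}")
    edges = prewitt_edges(eye_raster)

    best_score = -np.inf
    best: tuple[int, int, int] | None = None
    for r in range(r_lo, r_hi + 1):
        response = ndimage.convolve(edges, _ring_kernel(r), mode="constant")
        idx = np.unravel_index(int(np.argmax(response)), response.shape)
        score = float(response[idx])
        if score > best_score + 1e-12:
            best_score = score
            best = (idx[1], idx[0], r)
    if best is None or best_score < min_support:
        raise NoIrisError(
            f"no circular blob with edge support >= {min_support} "
            f"(best {best_score:.2f})"
        )
    cx, cy, r = best
    return IrisLocation(float(cx), float(cy), float(r))


@dataclass(frozen=True)
class BrightnessProfile:
    """Horizontal lightness slice through the iris center."""

    values: np.ndarray
    center_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.center_index < len(self.values):
            raise ValueError("center_index outside profile")


def brightness_profile(
    l_raster: np.ndarray,
    iris: IrisLocation,
    half_length_factor: float = 2.0,
) -> BrightnessProfile:
    """Sample L values along y = iris center, +- half_length around it.

    ``half_length = round(half_length_factor * radius)`` must exceed the
    iris radius (the profile has to reach past the iris into the sclera);
    the window is clipped at the raster edge with the center index adjusted.
    """
    l_raster = np.asarray(l_raster, dtype=float)
    if half_length_factor < 1:
        raise ValueError("half_length_factor must be >= 1")
    h, w = l_raster.shape
    cy, cx = int(round(iris.center_y)), int(round(iris.center_x))
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError(f"iris center ({cx}, {cy}) outside raster {w}x{h}")
    half = int(round(half_length_factor * iris.radius))
    x0, x1 = max(0, cx - half), min(w - 1, cx + half)
    values = l_raster[cy, x0 : x1 + 1]
    return BrightnessProfile(values=values, center_index=cx - x0)


@dataclass(frozen=True)
class ScleraBrightness:
    """Peak lightness of the sclera flanks left/right of the iris span."""

    LR: float
    RR: float


def sclera_peaks(profile: BrightnessProfile, iris_radius: float) -> ScleraBrightness:
    """Max brightness on each side of the excluded iris span.

    The span [center - r, center + r] belongs to the iris and is excluded;
    an empty flank (profile too short) raises
    :class:`DegenerateProfileError`.
    """
    r = int(round(iris_radius))
    c = profile.center_index
    left = profile.values[: max(0, c - r)]
    right = profile.values[c + r + 1 :]
    if left.size == 0 or right.size == 0:
        raise DegenerateProfileError(
            "profile does not extend beyond the iris on both sides"
        )
    return ScleraBrightness(LR=float(left.max()), RR=float(right.max()))


def sclera_peak_distances(
    profile: BrightnessProfile, iris_radius: float
) -> ScleraBrightness:
    """Alternate reading of (LR, RR): pixel distances from the iris center
    to the brightest pixel of each flank (the "distance ratio"
    interpretation, available behind the ``distance_ratio`` config switch).
    """
    r = int(round(iris_radius))
    c = profile.center_index
    left = profile.values[: max(0, c - r)]
    right = profile.values[c + r + 1 :]
    if left.size == 0 or right.size == 0:
        raise DegenerateProfileError(
            "profile does not extend beyond the iris on both sides"
        )
    li = int(np.argmax(left))
    ri = int(np.argmax(right)) + c + r + 1
    return ScleraBrightness(LR=float(c - li), RR=float(ri - c))


def classify_gaze(sb: ScleraBrightness, threshold: float = DEFAULT_THRESHOLD) -> GazeLabel:
    """Apply the ratio rule to one eye's (LR, RR) pair.

    Exactly one of the three cases fires for every positive pair when
    t < 1; equality at the threshold is inclusive (ratio == t is lateral).
    Both peaks zero is degenerate.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if sb.LR == 0 and sb.RR == 0:
        raise DegenerateProfileError("both sclera peaks are zero")
    if sb.LR == sb.RR:
        # Perfect symmetry is central gaze even at t = 1, where both
        # lateral conditions would otherwise fire simultaneously.
        return GazeLabel.CENTER
    if sb.RR > 0 and sb.LR / sb.RR <= threshold:
        return GazeLabel.RIGHT
    if sb.LR > 0 and sb.RR / sb.LR <= threshold:
        return GazeLabel.LEFT
    return GazeLabel.CENTER


@dataclass(frozen=True)
class GazeConfig:
    """Everything the per-frame classifier needs beyond the detections."""

    threshold: float = DEFAULT_THRESHOLD
    half_length_factor: float = 2.0
    distance_ratio: bool = False
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    iris_min_support: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.half_length_factor < 1:
            raise ValueError("half_length_factor must be >= 1")


@dataclass(frozen=True)
class EyeDiagnostics:
    """Audit record for one eye in one frame."""

    side: str  # "left" | "right" in image coordinates
    iris: IrisLocation | None = None
    LR: float | None = None
    RR: float | None = None
    ratio: float | None = None  # min(LR, RR) / max(LR, RR)
    label: GazeLabel | None = None
    failure: str | None = None


@dataclass(frozen=True)
class FrameDiagnostics:
    label: GazeLabel
    eyes: tuple[EyeDiagnostics, ...]
    reason: str | None = None  # why DISTRACTION, when it is


@dataclass(frozen=True)
class EyeFeatures:
    """Model-independent per-eye evidence: iris circle + lightness raster.

    Extraction (enhancement + iris localization) is the expensive stage and
    does not depend on the decision threshold or profile length, so
    calibration extracts once and sweeps the cheap rule stage over a grid.
    """

    iris: IrisLocation | None
    light: np.ndarray | None
    failure: str | None = None


def extract_eye_features(
    frame: np.ndarray, eye: Region, config: GazeConfig = GazeConfig()
) -> EyeFeatures:
    """Locate the iris on the black-enhanced (K, gamma-3) channel of the eye
    crop and prepare the contrast-remapped L raster for profiling.
    Failures are captured, never raised."""
    crop = eye.crop(validate_rgb(frame))
    try:
        dark = black_region_enhance(crop, config.enhance)
        iris = locate_iris(dark, min_support=config.iris_min_support)
        light = enhanced_lightness(crop, config.enhance)
    except (NoIrisError, ValueError) as exc:
        return EyeFeatures(None, None, failure=f"{type(exc).__name__}: {exc}")
    return EyeFeatures(iris=iris, light=light)


def classify_eye_features(
    feat: EyeFeatures, config: GazeConfig = GazeConfig(), side: str = "?"
) -> EyeDiagnostics:
    """Profile + sclera peaks + ratio rule on pre-extracted eye features."""
    if feat.failure is not None:
        return EyeDiagnostics(side=side, failure=feat.failure)
    try:
        profile = brightness_profile(feat.light, feat.iris, config.half_length_factor)
        reader = sclera_peak_distances if config.distance_ratio else sclera_peaks
        sb = reader(profile, feat.iris.radius)
        label = classify_gaze(sb, config.threshold)
    except (DegenerateProfileError, ValueError) as exc:
        return EyeDiagnostics(
            side=side, iris=feat.iris, failure=f"{type(exc).__name__}: {exc}"
        )
    hi = max(sb.LR, sb.RR)
    return EyeDiagnostics(
        side=side,
        iris=feat.iris,
        LR=sb.LR,
        RR=sb.RR,
        ratio=min(sb.LR, sb.RR) / hi if hi > 0 else None,
        label=label,
    )


def classify_eye(
    frame: np.ndarray, eye: Region, config: GazeConfig = GazeConfig(), side: str = "?"
) -> EyeDiagnostics:
    """Run iris localization + profile + ratio rule on one eye region."""
    return classify_eye_features(extract_eye_features(frame, eye, config), config, side)


def classify_frame(
    frame: np.ndarray,
    detection: DetectionResult,
    config: GazeConfig = GazeConfig(),
) -> FrameDiagnostics:
    """Per-frame label from both eyes.

    DISTRACTION when both eyes were not simultaneously detected, when any
    per-eye stage degenerates, or when the two eyes disagree (the gaze is
    confidently on neither scene); otherwise the shared per-eye label.
    """
    if not detection.both_eyes_found:
        return FrameDiagnostics(
            label=GazeLabel.DISTRACTION, eyes=(), reason="both eyes not detected"
        )
    left = classify_eye(frame, detection.left_eye, config, side="left")
    right = classify_eye(frame, detection.right_eye, config, side="right")
    return combine_eye_diagnostics(left, right)


def classify_frame_features(
    features: tuple[EyeFeatures, EyeFeatures] | None,
    config: GazeConfig = GazeConfig(),
) -> FrameDiagnostics:
    """Frame label from pre-extracted per-eye features (None = eyes missing)."""
    if features is None:
        return FrameDiagnostics(
            label=GazeLabel.DISTRACTION, eyes=(), reason="both eyes not detected"
        )
    left = classify_eye_features(features[0], config, side="left")
    right = classify_eye_features(features[1], config, side="right")
    return combine_eye_diagnostics(left, right)


def extract_frame_features(
    frame: np.ndarray,
    detection: DetectionResult,
    config: GazeConfig = GazeConfig(),
) -> tuple[EyeFeatures, EyeFeatures] | None:
    """Per-eye features for a frame, or None when both eyes were not found."""
    if not detection.both_eyes_found:
        return None
    return (
        extract_eye_features(frame, detection.left_eye, config),
        extract_eye_features(frame, detection.right_eye, config),
    )


def combine_eye_diagnostics(
    left: EyeDiagnostics, right: EyeDiagnostics
) -> FrameDiagnostics:
    eyes = (left, right)
    if left.failure or right.failure:
        return FrameDiagnostics(
            label=GazeLabel.DISTRACTION, eyes=eyes, reason="per-eye stage failed"
        )
    if left.label is right.label:
        return FrameDiagnostics(label=left.label, eyes=eyes)
    return FrameDiagnostics(
        label=GazeLabel.DISTRACTION, eyes=eyes, reason="eyes disagree"
    )
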