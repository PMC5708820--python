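"""Face and eye localization with a decision-tree fallback chain.

The chain mirrors a cascade-classification pipeline: detect the face first
(to narrow the search and save time), then the two-eye region, then each
individual eye.  If the face is not found, eye search proceeds on the whole
frame rather than aborting.  A frame in which both eyes are not
simultaneously found is a distraction by definition.

Face detection uses a pretrained multi-scale sliding-window cascade
(scikit-image's LBP frontal-face model by default; any model file in the
same XML format can be supplied).  No pretrained eye cascade ships with the
scientific Python stack, so individual eyes are found by a dark-blob search
(K-channel connected components in the upper face half).  For synthetic
fixtures and any source with known geometry, bypass mode injects
ground-truth regions verbatim, making every downstream stage a deterministic
function of pixel content only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from skimage import measure
from skimage.data import lbp_frontal_face_cascade_filename
from skimage.feature import Cascade

from .enhance import k_channel
from .fixtures import FaceTruth
from .types import Region, validate_rgb


@dataclass(frozen=True)
class DetectorConfig:
    """Tuning knobs of the detection chain (conventional defaults)."""

    face_cascade_path: str | None = None  # None -> bundled LBP model
    scale_factor: float = 1.2
    step_ratio: float = 1.0
    min_size_frac: float = 0.1  # of min(frame height, width)
    max_size_frac: float = 0.9
    eye_k_quantile: float = 0.85  # K-channel threshold for dark-blob eyes
    eye_min_area_frac: float = 0.001  # of face area


@dataclass(frozen=True)
class DetectionResult:
    """Regions found in one frame; ``both_eyes_found`` drives the taxonomy."""

    face: Region | None = None
    eye_pair: Region | None = None
    left_eye: Region | None = None
    right_eye: Region | None = None

    @property
    def both_eyes_found(self) -> bool:
        return self.left_eye is not None and self.right_eye is not None


@lru_cache(maxsize=4)
def _load_cascade(path: str) -> Cascade:
    if not Path(path).exists():
        raise FileNotFoundError(f"cascade model file not found: {path}")
    return Cascade(path)


def detect_face(
    frame: np.ndarray, config: DetectorConfig = DetectorConfig()
) -> Region | None:
    """Largest detected frontal face, or None.

    Multiple candidates keep the largest; ties break toward smaller x
    (single-subject assumption).
    """
    frame = validate_rgb(frame)
    path = config.face_cascade_path or lbp_frontal_face_cascade_filename()
    cascade = _load_cascade(str(path))
    short = min(frame.shape[:2])
    lo = max(16, int(short * config.min_size_frac))
    hi = max(lo + 1, int(short * config.max_size_frac))
    hits = cascade.detect_multi_scale(
        img=frame,
        scale_factor=config.scale_factor,
        step_ratio=config.step_ratio,
        min_size=(lo, lo),
        max_size=(hi, hi),
    )
    if not hits:
        return None
    regions = [Region(h["c"], h["r"], h["width"], h["height"]) for h in hits]
    return max(regions, key=lambda r: (r.area, -r.x))


def _dark_blob_box(
    k: np.ndarray, origin: tuple[int, int], quantile: float, min_area: int
) -> Region | None:
    """Bounding box of the largest dark blob in a K-channel patch."""
    if k.size == 0:
        return None
    thr = np.quantile(k, quantile)
    mask = k >= max(thr, k.min() + 1e-6)
    labels = measure.label(mask)
    if labels.max() == 0:
        return None
    best = None
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        if best is None or prop.area > best.area:
            best = prop
    if best is None:
        return None
    r0, c0, r1, c1 = best.bbox
    # pad to include surrounding sclera; clamp to patch
    pr = max(2, (r1 - r0) // 2)
    pc = max(2, (c1 - c0))
    r0, c0 = max(0, r0 - pr), max(0, c0 - pc)
    r1, c1 = min(k.shape[0], r1 + pr), min(k.shape[1], c1 + pc)
    oy, ox = origin
    return Region(ox + c0, oy + r0, c1 - c0, r1 - r0)


def detect_eyes(
    frame: np.ndarray,
    face: Region | None,
    config: DetectorConfig = DetectorConfig(),
) -> DetectionResult:
    """Locate both eyes inside the face (whole frame when no face).

    The eye-pair band is the upper-middle stripe of the search window; each
    half is searched for its darkest compact blob (the iris).  Both single
    eyes must be found for ``both_eyes_found``; the eye-pair box is their
    union.
    """
    frame = validate_rgb(frame)
    if face is not None:
        search = face
    else:
        search = Region(0, 0, frame.shape[1], frame.shape[0])
    # Eyes sit in the upper half of a frontal face, below the forehead.
    band = Region(
        search.x,
        search.y + int(0.2 * search.h),
        search.w,
        max(1, int(0.45 * search.h)),
    )
    k = k_channel(frame)
    min_area = max(4, int(config.eye_min_area_frac * search.area))
    half_w = band.w // 2
    left_patch = k[band.y : band.y2, band.x : band.x + half_w]
    right_patch = k[band.y : band.y2, band.x + half_w : band.x2]
    left = _dark_blob_box(
        left_patch, (band.y, band.x), config.eye_k_quantile, min_area
    )
    right = _dark_blob_box(
        right_patch, (band.y, band.x + half_w), config.eye_k_quantile, min_area
    )
    pair = None
    if left and right:
        x0, y0 = min(left.x, right.x), min(left.y, right.y)
        x1, y1 = max(left.x2, right.x2), max(left.y2, right.y2)
        pair = Region(x0, y0, x1 - x0, y1 - y0)
    return DetectionResult(face=face, eye_pair=pair, left_eye=left, right_eye=right)


def detect_frame(
    frame: np.ndarray, config: DetectorConfig = DetectorConfig()
) -> DetectionResult:
    """Full chain: face, then eyes (falling back to whole-frame search)."""
    face = detect_face(frame, config)
    return detect_eyes(frame, face, config)


def detection_from_truth(truth: FaceTruth) -> DetectionResult:
    """Bypass mode: return injected ground-truth regions verbatim."""
    pair = None
    if truth.left_eye and truth.right_eye:
        le, re = truth.left_eye, truth.right_eye
        x0, y0 = min(le.x, re.x), min(le.y, re.y)
        x1, y1 = max(le.x2, re.x2), max(le.y2, re.y2)
        pair = Region(x0, y0, x1 - x0, y1 - y0)
    return DetectionResult(
        face=truth.face,
        eye_pair=pair,
        left_eye=truth.left_eye,
        right_eye=truth.right_eye,
    )
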