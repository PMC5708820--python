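"""Synthetic faces, eyes, sessions and cohorts with known ground truth.

The renderer emulates what the gaze classifier actually consumes: a frontal
face with two eyes, each a bright sclera ellipse with a dark iris disc whose
lateral position encodes the gaze.  The sign convention follows the
brightness-ratio rule with an un-mirrored front camera: a subject looking at
the LEFT half of the screen turns the eyes so the iris sits toward image
*right* (positive offset), leaving the bright sclera on the image-left flank
of the iris.  ``iris_offset_for_label`` encodes this once for the whole
package.

A lateral gaze places the iris flush against the sclera boundary (the
physical extreme: the iris abuts the eye corner, so no bright sclera remains
on the occluded side).  Rendering is exactly mirror-symmetric: flipping a
rendered frame horizontally equals rendering with negated offsets and
swapped eye boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .types import GazeLabel, IrisLocation, Region, validate_rgb

#: Default gray levels, chosen once to mimic the relevant contrasts of a
#: webcam face frame: bright sclera, dark iris, mid skin.
SCLERA_COLOR = (235, 235, 235)
IRIS_COLOR = (45, 45, 45)
SKIN_COLOR = (190, 150, 120)
BACKGROUND_COLOR = (60, 60, 60)


@dataclass(frozen=True)
class EyeRenderSpec:
    """Parameters for rendering one synthetic eye region.

    ``iris_offset`` is the signed lateral displacement (pixels) of the iris
    center from the eye center; positive = toward increasing x.
    """

    image_size: tuple[int, int] = (56, 36)  # (width, height)
    sclera_color: tuple[int, int, int] = SCLERA_COLOR
    iris_color: tuple[int, int, int] = IRIS_COLOR
    skin_color: tuple[int, int, int] = SKIN_COLOR
    iris_radius: int = 7
    iris_offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def sclera_semi_axes(self) -> tuple[float, float]:
        """(ax, ay): horizontal/vertical semi-axes of the sclera ellipse."""
        w, h = self.image_size
        return (w / 2 - 2, h / 2 - 2)

    @property
    def max_offset(self) -> float:
        """Largest legal |iris_offset|: the iris may touch the sclera edge."""
        return self.sclera_semi_axes[0] - self.iris_radius

    def validate(self) -> None:
        w, h = self.image_size
        ax, ay = self.sclera_semi_axes
        if w < 8 or h < 8:
            raise ValueError(f"eye image too small: {w}x{h}")
        if self.iris_radius <= 0:
            raise ValueError("iris_radius must be > 0")
        if self.iris_radius > min(ax, ay):
            raise ValueError(
                f"iris (r={self.iris_radius}) does not fit inside the "
                f"sclera ellipse (semi-axes {ax:.1f}, {ay:.1f})"
            )
        if abs(self.iris_offset) > self.max_offset + 1e-9:
            raise ValueError(
                f"|iris_offset|={abs(self.iris_offset)} exceeds eye "
                f"half-width minus iris radius ({self.max_offset:.1f})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def iris_offset_for_label(label: GazeLabel, spec: EyeRenderSpec) -> float:
    """Iris offset that realizes ``label`` for one eye under the ratio rule.

    LEFT gaze -> iris toward image right (+), RIGHT gaze -> image left (-),
    CENTER -> centered.  Lateral offsets sit at the sclera boundary so the
    occluded flank of the brightness profile falls on skin, not sclera.
    """
    d = spec.max_offset
    if label is GazeLabel.LEFT:
        return d
    if label is GazeLabel.RIGHT:
        return -d
    if label is GazeLabel.CENTER:
        return 0.0
    raise ValueError(f"no iris offset renders label {label}")


def render_eye(spec: EyeRenderSpec) -> tuple[np.ndarray, IrisLocation]:
    """Render one eye region; return the RGB raster and the true iris circle.

    The raster is skin-colored with a bright sclera ellipse centered in the
    box and a dark iris disc at the specified lateral offset.  With the same
    spec (including seed) the output is bit-identical across calls, and the
    geometry is symmetric about the box center so that mirroring the raster
    equals rendering with a negated offset.
    """
    spec.validate()
    w, h = spec.image_size
    ax, ay = spec.sclera_semi_axes
    cx, cy = (w - 1) / 2, (h - 1) / 2
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.skin_color

    sclera = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    img[sclera] = spec.sclera_color

    icx = cx + spec.iris_offset
    iris = (xx - icx) ** 2 + (yy - cy) ** 2 <= spec.iris_radius**2
    img[iris] = spec.iris_color

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return out, IrisLocation(icx, cy, float(spec.iris_radius))


@dataclass(frozen=True)
class FaceLayout:
    """Placement of the face and the two eye boxes inside a frame."""

    image_size: tuple[int, int] = (192, 128)  # (width, height)
    face: Region = field(default_factory=lambda: Region(28, 8, 136, 112))
    left_eye: Region = field(default_factory=lambda: Region(36, 44, 56, 36))
    right_eye: Region = field(default_factory=lambda: Region(100, 44, 56, 36))

    def validate(self) -> None:
        w, h = self.image_size
        frame = Region(0, 0, w, h)
        if not frame.contains(self.face):
            raise ValueError("face box outside the frame")
        for name, eye in (("left", self.left_eye), ("right", self.right_eye)):
            if not self.face.contains(eye):
                raise ValueError(f"{name} eye box outside the face box")
        if self.left_eye.intersects(self.right_eye):
            raise ValueError("eye boxes overlap")
        if self.left_eye.x >= self.right_eye.x:
            raise ValueError("left eye must have smaller x than right eye")

    def mirrored(self) -> "FaceLayout":
        w = self.image_size[0]
        return FaceLayout(
            image_size=self.image_size,
            face=self.face.mirrored(w),
            left_eye=self.right_eye.mirrored(w),
            right_eye=self.left_eye.mirrored(w),
        )


@dataclass(frozen=True)
class FaceTruth:
    """Ground-truth regions emitted alongside a rendered frame.

    Absent eyes (occluded / not rendered) carry ``None``; iris locations are
    in full-frame coordinates.
    """

    face: Region | None
    left_eye: Region | None
    right_eye: Region | None
    left_iris: IrisLocation | None
    right_iris: IrisLocation | None

    @property
    def both_eyes_present(self) -> bool:
        return self.left_eye is not None and self.right_eye is not None

    def mirrored(self, image_width: int) -> "FaceTruth":
        """Ground truth after horizontal mirroring: eye boxes swap sides."""

        def flip_iris(iris: IrisLocation | None) -> IrisLocation | None:
            if iris is None:
                return None
            return IrisLocation(
                image_width - 1 - iris.center_x, iris.center_y, iris.radius
            )

        return FaceTruth(
            face=self.face.mirrored(image_width) if self.face else None,
            left_eye=(
                self.right_eye.mirrored(image_width) if self.right_eye else None
            ),
            right_eye=(
                self.left_eye.mirrored(image_width) if self.left_eye else None
            ),
            left_iris=flip_iris(self.right_iris),
            right_iris=flip_iris(self.left_iris),
        )


def render_face(
    left_spec: EyeRenderSpec | None,
    right_spec: EyeRenderSpec | None,
    layout: FaceLayout | None = None,
) -> tuple[np.ndarray, FaceTruth]:
    """Compose a frontal-face frame from two eye renders.

    Passing ``None`` for an eye spec leaves that eye occluded (skin only),
    which downstream classification must register as a distraction.
    """
    layout = layout or FaceLayout()
    layout.validate()
    w, h = layout.image_size
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = BACKGROUND_COLOR

    face = layout.face
    yy, xx = np.mgrid[0 : face.h, 0 : face.w].astype(float)
    fcx, fcy = (face.w - 1) / 2, (face.h - 1) / 2
    ellipse = ((xx - fcx) / (face.w / 2)) ** 2 + ((yy - fcy) / (face.h / 2)) ** 2 <= 1
    patch = img[face.y : face.y2, face.x : face.x2]
    patch[ellipse] = SKIN_COLOR

    irises: dict[str, IrisLocation | None] = {"left": None, "right": None}
    for name, spec, box in (
        ("left", left_spec, layout.left_eye),
        ("right", right_spec, layout.right_eye),
    ):
        if spec is None:
            continue
        if spec.image_size != (box.w, box.h):
            spec = replace(spec, image_size=(box.w, box.h))
        eye_img, iris = render_eye(spec)
        img[box.y : box.y2, box.x : box.x2] = eye_img
        irises[name] = IrisLocation(
            iris.center_x + box.x, iris.center_y + box.y, iris.radius
        )

    truth = FaceTruth(
        face=face,
        left_eye=layout.left_eye if left_spec is not None else None,
        right_eye=layout.right_eye if right_spec is not None else None,
        left_iris=irises["left"],
        right_iris=irises["right"],
    )
    return validate_rgb(img), truth


@dataclass(frozen=True)
class SessionSpec:
    """A whole synthetic recording session with known per-frame labels."""

    true_labels: Sequence[GazeLabel]
    fps: float = 60.0
    face_present: Sequence[bool] | None = None
    noise_sd: float = 0.0
    layout: FaceLayout = field(default_factory=FaceLayout)
    eye_template: EyeRenderSpec = field(default_factory=EyeRenderSpec)
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.true_labels)

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.fps

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("session must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.face_present is not None and len(self.face_present) != self.n_frames:
            raise ValueError("face_present length must match true_labels")


def generate_session(
    spec: SessionSpec,
) -> Iterator[tuple[np.ndarray, FaceTruth, GazeLabel]]:
    """Yield (frame, ground-truth regions, true label) per frame, in order.

    LEFT/RIGHT/CENTER frames render both eyes with the label's iris offset;
    DISTRACTION frames either omit the whole face (``face_present`` false)
    or occlude one eye, alternating sides deterministically.
    """
    spec.validate()
    present = spec.face_present or [True] * spec.n_frames
    template = replace(spec.eye_template, noise_sd=spec.noise_sd)
    # Child seeds: one per frame/eye, derived from the session seed.
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * spec.n_frames)
    seeds = (seeds % np.int64(2**31)).astype(np.int64)

    for i, label in enumerate(spec.true_labels):
        ls = replace(template, seed=int(seeds[2 * i]))
        rs = replace(template, seed=int(seeds[2 * i + 1]))
        if not present[i]:
            w, h = spec.layout.image_size
            frame = np.full((h, w, 3), BACKGROUND_COLOR, dtype=np.uint8)
            yield frame, FaceTruth(None, None, None, None, None), label
            continue
        if label is GazeLabel.DISTRACTION:
            # Occlude one eye; alternate so neither side is systematic.
            if i % 2 == 0:
                frame, truth = render_face(ls, None, spec.layout)
            else:
                frame, truth = render_face(None, rs, spec.layout)
        else:
            off = iris_offset_for_label(label, template)
            frame, truth = render_face(
                replace(ls, iris_offset=off),
                replace(rs, iris_offset=off),
                spec.layout,
            )
        yield frame, truth, label


def session_truth_table(spec: SessionSpec) -> pd.DataFrame:
    """Ground-truth label table for a session (frame_index, label)."""
    return pd.DataFrame(
        {
            "frame_index": np.arange(spec.n_frames),
            "label": [lab.value for lab in spec.true_labels],
        }
    )


@dataclass(frozen=True)
class CohortSpec:
    """Per-subject social-preference cohorts with known group means.

    Preference fractions are drawn from Beta distributions with the stated
    means; ``dispersion`` is the Beta concentration (alpha + beta) — larger
    values give tighter spread around the group mean.
    """

    n_per_group: dict[str, int]
    group_mean_social: dict[str, float]
    dispersion: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_per_group) != set(self.group_mean_social):
            raise ValueError("group names must match between sizes and means")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have n >= 1, got {n}")
        for g, m in self.group_mean_social.items():
            if not 0 < m < 1:
                raise ValueError(f"group mean for {g!r} must be in (0, 1), got {m}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table (subject_id, group, social_fraction)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in sorted(spec.n_per_group):
        n = spec.n_per_group[group]
        m = spec.group_mean_social[group]
        alpha = m * spec.dispersion
        beta = (1 - m) * spec.dispersion
        draws = rng.beta(alpha, beta, size=n)
        for j, x in enumerate(draws):
            rows.append(
                {
                    "subject_id": f"{group}-{j:04d}",
                    "group": group,
                    "social_fraction": float(x),
                }
            )
    return pd.DataFrame(rows)
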