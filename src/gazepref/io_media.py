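"""Frame extraction, subsampling, and table I/O.

"Video" inputs come in two forms: a directory of numbered PNG/JPEG frames
(the canonical on-disk session format written by the simulator) or a video
container decoded through imageio when a suitable plugin is available.
Annotation, ground-truth-region, subject, and session-result tables are
plain CSV/JSON.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .fixtures import FaceTruth
from .types import GazeLabel, IrisLocation, Region, Scene

FRAME_EXTENSIONS = (".png", ".jpg", ".jpeg")


class EmptySessionError(RuntimeError):
    """Raised when a session source yields no frames."""


class AnnotationSource(enum.Enum):
    MANUAL = "MANUAL"
    AUTO = "AUTO"


@dataclass(frozen=True)
class SubjectRecord:
    """Anonymous per-subject metadata."""

    subject_id: str
    age_months: float
    sex: str  # "F" | "M"
    weight_kg: float
    height_cm: float
    group: str  # "ASD" | "NON_ASD"

    def __post_init__(self) -> None:
        if self.age_months <= 0:
            raise ValueError("age_months must be positive")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.group not in ("ASD", "NON_ASD"):
            raise ValueError(f"group must be ASD or NON_ASD, got {self.group!r}")


@dataclass(frozen=True)
class StimulusConfig:
    """Geometry and timing of the two-scene stimulus protocol.

    Defaults follow the preferential-looking protocol this package targets:
    five 50-second segments at 60 fps preceded by a 10-second attention
    grabber (excluded from analysis), social scene on the right half of the
    screen and abstract scene on the left.
    """

    segment_seconds: float = 50.0
    fps: float = 60.0
    n_videos: int = 5
    intro_seconds: float = 10.0
    left_scene: Scene = Scene.ABSTRACT
    right_scene: Scene = Scene.SOCIAL

    def __post_init__(self) -> None:
        if self.left_scene == self.right_scene:
            raise ValueError("left and right scenes must differ")
        if self.fps <= 0 or self.segment_seconds <= 0:
            raise ValueError("fps and segment_seconds must be positive")
        if self.n_videos < 1:
            raise ValueError("n_videos must be >= 1")
        if self.intro_seconds < 0:
            raise ValueError("intro_seconds must be >= 0")

    @property
    def frames_per_segment(self) -> int:
        return int(round(self.segment_seconds * self.fps))

    @property
    def intro_frames(self) -> int:
        return int(round(self.intro_seconds * self.fps))

    @property
    def total_frames(self) -> int:
        """Protocol frame budget across all segments (intro excluded)."""
        return self.n_videos * self.frames_per_segment

    def scene_for_label(self, label: GazeLabel) -> Scene | None:
        if label is GazeLabel.LEFT:
            return self.left_scene
        if label is GazeLabel.RIGHT:
            return self.right_scene
        return None


def _frame_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in FRAME_EXTENSIONS
    )
    return files


def extract_frames(
    video_path: str | Path,
    config: StimulusConfig | None = None,
    *,
    skip_intro: bool = False,
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (frame_index, RGB frame) in temporal order from a session source.

    ``video_path`` may be a directory of numbered still images or a video
    container.  At most ``segment_seconds * fps`` frames are yielded; shorter
    sessions are allowed (uncooperative subjects routinely end early).  With
    ``skip_intro`` the first ``intro_seconds`` worth of frames is dropped and
    indices restart at 0 for the analysed segment.

    Raises ``FileNotFoundError`` for a missing source and
    ``EmptySessionError`` when no frames are found.
    """
    config = config or StimulusConfig()
    path = Path(video_path)
    if not path.exists():
        raise FileNotFoundError(f"no such video source: {path}")

    limit = config.frames_per_segment
    skip = config.intro_frames if skip_intro else 0

    if path.is_dir():
        files = _frame_files(path)
        if not files:
            raise EmptySessionError(f"no frames found in {path}")
        source: Iterable[np.ndarray] = (iio.imread(f) for f in files[skip:])
    else:
        try:
            source = iio.imiter(path)
        except Exception as exc:  # no decoder / corrupt file
            raise IOError(f"cannot decode video container {path}: {exc}") from exc

    n = 0
    for i, frame in enumerate(source):
        if not path.is_dir() and i < skip:
            continue
        if n >= limit:
            break
        frame = np.asarray(frame)
        if frame.ndim == 2:  # grayscale still -> RGB
            frame = np.stack([frame] * 3, axis=-1)
        yield n, frame[..., :3]
        n += 1
    if n == 0:
        raise EmptySessionError(f"session source {path} produced no frames")


def write_frames(frames: Iterable[np.ndarray], directory: str | Path) -> int:
    """Write frames as zero-padded numbered PNGs; return the count."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = 0
    for i, frame in enumerate(frames):
        iio.imwrite(directory / f"frame_{i:06d}.png", frame)
        n += 1
    return n


def subsample(items: Sequence, stride: int) -> list:
    """Keep elements at positions 0, stride, 2*stride, ...

    This realizes every-k-th-frame manual annotation; stride 1 is identity
    and a stride beyond the length keeps exactly the first element.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return list(items[::stride])


def subsample_table(table: pd.DataFrame, stride: int) -> pd.DataFrame:
    """Row-subsample an annotation table by frame position."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return table.iloc[::stride].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Annotation tables


def _validate_annotations(table: pd.DataFrame) -> pd.DataFrame:
    valid = {lab.value for lab in GazeLabel}
    bad = set(table["label"]) - valid
    if bad:
        raise ValueError(f"unknown gaze labels: {sorted(bad)}")
    idx = table["frame_index"].to_numpy()
    if len(idx) > 1 and not (np.diff(idx) > 0).all():
        raise ValueError("frame indices must be strictly increasing")
    return table


def make_annotations(
    frame_indices: Sequence[int],
    labels: Sequence[GazeLabel | str],
    source: AnnotationSource = AnnotationSource.AUTO,
) -> pd.DataFrame:
    """Build an annotation table (frame_index, label) with a source tag."""
    table = pd.DataFrame(
        {
            "frame_index": np.asarray(frame_indices, dtype=int),
            "label": [
                lab.value if isinstance(lab, GazeLabel) else str(lab)
                for lab in labels
            ],
        }
    )
    table = _validate_annotations(table)
    table.attrs["source"] = source.value
    return table


def read_annotations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype={"frame_index": int, "label": str})
    except Exception as exc:
        raise ValueError(f"malformed annotation CSV {path}: {exc}") from exc
    if list(table.columns[:2]) != ["frame_index", "label"]:
        raise ValueError(
            f"{path}: expected header frame_index,label, got {list(table.columns)}"
        )
    for row, lab in enumerate(table["label"]):
        if lab not in {g.value for g in GazeLabel}:
            raise ValueError(f"{path} row {row + 2}: unknown label {lab!r}")
    return _validate_annotations(table)


def write_annotations(table: pd.DataFrame, path: str | Path) -> None:
    _validate_annotations(table)
    table.to_csv(path, index=False)


def labels_from_table(table: pd.DataFrame) -> list[GazeLabel]:
    return [GazeLabel(lab) for lab in table["label"]]


# ---------------------------------------------------------------------------
# Ground-truth region tables (detection bypass format)

_TRUTH_COLUMNS = [
    "frame_index", "label",
    "face_x", "face_y", "face_w", "face_h",
    "left_eye_x", "left_eye_y", "left_eye_w", "left_eye_h",
    "right_eye_x", "right_eye_y", "right_eye_w", "right_eye_h",
    "left_iris_x", "left_iris_y", "left_iris_r",
    "right_iris_x", "right_iris_y", "right_iris_r",
]


def _region_cells(region: Region | None) -> list:
    return [region.x, region.y, region.w, region.h] if region else [""] * 4


def _iris_cells(iris: IrisLocation | None) -> list:
    return [iris.center_x, iris.center_y, iris.radius] if iris else [""] * 3


def truth_to_row(frame_index: int, truth: FaceTruth, label: GazeLabel) -> list:
    return (
        [frame_index, label.value]
        + _region_cells(truth.face)
        + _region_cells(truth.left_eye)
        + _region_cells(truth.right_eye)
        + _iris_cells(truth.left_iris)
        + _iris_cells(truth.right_iris)
    )


def write_truth(rows: Iterable[list], path: str | Path) -> None:
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, index=False)


def _cell_region(row: pd.Series, prefix: str) -> Region | None:
    x = row[f"{prefix}_x"]
    if pd.isna(x) or x == "":
        return None
    return Region(
        int(row[f"{prefix}_x"]), int(row[f"{prefix}_y"]),
        int(row[f"{prefix}_w"]), int(row[f"{prefix}_h"]),
    )


def read_truth(path: str | Path) -> dict[int, FaceTruth]:
    """Read a ground-truth region CSV keyed by frame index."""
    table = pd.read_csv(path)
    out: dict[int, FaceTruth] = {}
    for _, row in table.iterrows():
        irises = {}
        for side in ("left", "right"):
            v = row[f"{side}_iris_x"]
            irises[side] = (
                None
                if pd.isna(v) or v == ""
                else IrisLocation(
                    float(row[f"{side}_iris_x"]),
                    float(row[f"{side}_iris_y"]),
                    float(row[f"{side}_iris_r"]),
                )
            )
        out[int(row["frame_index"])] = FaceTruth(
            face=_cell_region(row, "face"),
            left_eye=_cell_region(row, "left_eye"),
            right_eye=_cell_region(row, "right_eye"),
            left_iris=irises["left"],
            right_iris=irises["right"],
        )
    return out


# ---------------------------------------------------------------------------
# Session results / subject tables


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    table = pd.read_csv(path)
    return [
        SubjectRecord(
            subject_id=str(r["subject_id"]),
            age_months=float(r["age_months"]),
            sex=str(r["sex"]),
            weight_kg=float(r["weight_kg"]),
            height_cm=float(r["height_cm"]),
            group=str(r["group"]),
        )
        for _, r in table.iterrows()
    ]
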