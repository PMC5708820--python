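"""Session aggregation, threshold calibration, and validation statistics.

A session is a labeled frame sequence; its summary is the percentage of
accumulated viewing time per gaze category.  Scene percentages (social vs
abstract) use only the LEFT/RIGHT frames — distraction and central gaze are
attributable to neither scene — mapped to screen sides by the stimulus
configuration.  Validation against a human rater uses frame-level Spearman
correlation on the binary LEFT/RIGHT coding, a pooled two-sample proportion
z-test on scene proportions, Pearson correlation and a paired t-test across
per-subject percentages, and group comparison is a two-sample t-test on
per-subject social-scene percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import DetectionResult
from .gaze import (
    DEFAULT_THRESHOLD,
    GazeConfig,
    classify_frame,
    classify_frame_features,
    extract_frame_features,
)
from .io_media import StimulusConfig
from .types import LATERAL_LABELS, GazeLabel, Scene


class EmptySessionError(RuntimeError):
    pass


class InsufficientDataError(RuntimeError):
    pass


def round_pct(x: float, digits: int = 2) -> float:
    """Round half-up, the convention used in printed report tables."""
    q = 10**digits
    return math.floor(x * q + 0.5) / q


@dataclass(frozen=True)
class SessionResult:
    """Per-category frame counts and time-preference percentages."""

    counts: dict[GazeLabel, int]
    total_frames: int
    pct: dict[GazeLabel, float]
    pct_lr_only: dict[GazeLabel, float] | None  # None when no L/R frames
    scene_pct: dict[Scene, float] | None

    @property
    def n_lateral(self) -> int:
        return sum(self.counts[lab] for lab in LATERAL_LABELS)

    def to_dict(self) -> dict:
        return {
            "counts": {k.value: v for k, v in self.counts.items()},
            "total_frames": self.total_frames,
            "pct": {k.value: v for k, v in self.pct.items()},
            "pct_lr_only": (
                None
                if self.pct_lr_only is None
                else {k.value: v for k, v in self.pct_lr_only.items()}
            ),
            "scene_pct": (
                None
                if self.scene_pct is None
                else {k.value: v for k, v in self.scene_pct.items()}
            ),
        }


def aggregate(
    labels: pd.DataFrame,
    stim: StimulusConfig | None = None,
    camera_mirrored: bool = False,
) -> SessionResult:
    """Summarize an annotation table into category and scene percentages.

    Four-way percentages are over all frames; LEFT/RIGHT-only percentages
    (and scene percentages) restrict the denominator to the lateral frames,
    since neither distraction nor central gaze is time spent on a scene.
    With ``camera_mirrored`` the LEFT/RIGHT labels are swapped before scene
    mapping (front cameras that mirror the preview reverse image sides).
    """
    stim = stim or StimulusConfig()
    if len(labels) == 0:
        raise EmptySessionError("cannot aggregate an empty annotation table")
    seq = [GazeLabel(lab) for lab in labels["label"]]
    if camera_mirrored:
        flip = {GazeLabel.LEFT: GazeLabel.RIGHT, GazeLabel.RIGHT: GazeLabel.LEFT}
        seq = [flip.get(lab, lab) for lab in seq]
    counts = {lab: 0 for lab in GazeLabel}
    for lab in seq:
        counts[lab] += 1
    total = len(seq)
    pct = {lab: 100.0 * counts[lab] / total for lab in GazeLabel}

    n_lr = counts[GazeLabel.LEFT] + counts[GazeLabel.RIGHT]
    if n_lr == 0:
        return SessionResult(counts, total, pct, None, None)
    pct_lr = {lab: 100.0 * counts[lab] / n_lr for lab in LATERAL_LABELS}
    scene_pct = {
        stim.left_scene: pct_lr[GazeLabel.LEFT],
        stim.right_scene: pct_lr[GazeLabel.RIGHT],
    }
    return SessionResult(counts, total, pct, pct_lr, scene_pct)


def binomial_se(k: int, n: int) -> float:
    """Binomial standard error of a percentage: 100 * sqrt(p(1-p)/n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    p = k / n
    return 100.0 * math.sqrt(p * (1 - p) / n)


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    """Confidence interval (in %) for a binomial proportion.

    Wald by default; ``method="exact"`` gives Clopper-Pearson.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    p = k / n
    if method == "wald":
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * math.sqrt(p * (1 - p) / n)
        return 100 * max(0.0, p - half), 100 * min(1.0, p + half)
    if method == "exact":
        alpha = 1 - level
        lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
        return 100 * lo, 100 * hi
    raise ValueError(f"unknown CI method {method!r}")


def proportion_ztest(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Pooled two-sample proportion z-test; returns (z, p)."""
    if min(n1, n2) <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "larger":
        p = stats.norm.sf(z)
    elif alternative == "smaller":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return z, p


# ---------------------------------------------------------------------------
# Threshold calibration


@dataclass(frozen=True)
class CalibrationModel:
    """One candidate classifier configuration and its manual concordance."""

    config: GazeConfig
    concordance: float = float("nan")

    @property
    def threshold(self) -> float:
        return self.config.threshold


def make_model_grid(
    thresholds: Sequence[float] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95),
    half_length_factors: Sequence[float] = (1.5, 2.0, 3.0),
) -> list[CalibrationModel]:
    """Default calibration grid: 6 thresholds x 3 profile lengths = 18 models."""
    return [
        CalibrationModel(GazeConfig(threshold=t, half_length_factor=f))
        for t in thresholds
        for f in half_length_factors
    ]


def classification_concordance(
    manual: Sequence[GazeLabel], auto: Sequence[GazeLabel]
) -> float:
    """Fraction of manually LEFT/RIGHT-labeled frames the classifier matches."""
    pairs = [
        (m, a) for m, a in zip(manual, auto, strict=True) if m in LATERAL_LABELS
    ]
    if not pairs:
        raise InsufficientDataError("no manual LEFT/RIGHT frames to compare")
    return sum(m is a for m, a in pairs) / len(pairs)


def calibrate_threshold(
    frames: Sequence[tuple[np.ndarray, DetectionResult]],
    manual: Sequence[GazeLabel],
    grid: Iterable[CalibrationModel] | None = None,
) -> CalibrationModel:
    """Pick the model maximizing manual concordance on LEFT/RIGHT frames.

    Ties resolve to the smaller threshold (the more conservative lateral
    call).  The grid defaults to :func:`make_model_grid`.  Iris localization
    and enhancement do not depend on the swept parameters, so per-eye
    features are extracted once per distinct extraction configuration and
    the rule stage alone is re-run per model.
    """
    grid = list(grid) if grid is not None else make_model_grid()
    if not grid:
        raise ValueError("calibration grid is empty")
    if not any(m in LATERAL_LABELS for m in manual):
        raise InsufficientDataError("manual labels contain no LEFT/RIGHT frames")
    feature_cache: dict = {}
    best: CalibrationModel | None = None
    for model in grid:
        key = (model.config.enhance, model.config.iris_min_support)
        if key not in feature_cache:
            feature_cache[key] = [
                extract_frame_features(f, det, model.config) for f, det in frames
            ]
        auto = [
            classify_frame_features(ft, model.config).label
            for ft in feature_cache[key]
        ]
        c = classification_concordance(manual, auto)
        scored = CalibrationModel(model.config, c)
        if (
            best is None
            or c > best.concordance
            or (c == best.concordance and scored.threshold < best.threshold)
        ):
            best = scored
    return best


# ---------------------------------------------------------------------------
# Manual-vs-automatic concordance report


@dataclass(frozen=True)
class ConcordanceReport:
    frame_spearman_rho: float
    frame_spearman_p: float
    n_frames_compared: int
    proportion_z: float
    proportion_p: float
    subject_pearson_r: float | None = None
    subject_pearson_p: float | None = None
    paired_t: float | None = None
    paired_p: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _binary_lateral(labels: Sequence[GazeLabel]) -> np.ndarray:
    return np.array([1.0 if lab is GazeLabel.RIGHT else 0.0 for lab in labels])


def concordance(
    manual: pd.DataFrame,
    auto: pd.DataFrame,
    per_subject_pcts: pd.DataFrame | None = None,
    alternative: str = "two-sided",
) -> ConcordanceReport:
    """Manual-vs-automatic agreement statistics.

    Tables join on ``frame_index``; only frames labeled LEFT or RIGHT in
    *both* sources are retained (distraction and central frames are removed
    from both before comparison).  Spearman uses the binary LEFT/RIGHT
    coding with midrank ties.  ``per_subject_pcts`` (columns ``manual_pct``,
    ``auto_pct``, one row per subject or subject/video) adds the Pearson
    correlation and the paired t-test.
    """
    joined = manual.merge(auto, on="frame_index", suffixes=("_manual", "_auto"))
    lat = {lab.value for lab in LATERAL_LABELS}
    joined = joined[
        joined["label_manual"].isin(lat) & joined["label_auto"].isin(lat)
    ]
    if len(joined) < 3:
        raise InsufficientDataError(
            f"only {len(joined)} jointly LEFT/RIGHT frames; need >= 3"
        )
    m = _binary_lateral([GazeLabel(v) for v in joined["label_manual"]])
    a = _binary_lateral([GazeLabel(v) for v in joined["label_auto"]])
    if np.array_equal(m, a) and (m == m[0]).all():
        # Perfect agreement on a constant vector: correlation is undefined
        # by rank arithmetic but agreement is total.
        rho, rho_p = 1.0, 0.0
    else:
        rho, rho_p = stats.spearmanr(m, a)
    n = len(joined)
    z, zp = proportion_ztest(
        int(m.sum()), n, int(a.sum()), n, alternative=alternative
    )

    pear_r = pear_p = t_stat = t_p = None
    if per_subject_pcts is not None:
        x = per_subject_pcts["manual_pct"].to_numpy(dtype=float)
        y = per_subject_pcts["auto_pct"].to_numpy(dtype=float)
        if len(x) < 3:
            raise InsufficientDataError("need >= 3 subjects for Pearson/paired t")
        if np.allclose(x, y):
            pear_r, pear_p = (1.0, 0.0) if np.ptp(x) > 0 else (1.0, 0.0)
            t_stat, t_p = 0.0, 1.0
        else:
            pear_r, pear_p = stats.pearsonr(x, y)
            t_stat, t_p = stats.ttest_rel(x, y)
    return ConcordanceReport(
        frame_spearman_rho=float(rho),
        frame_spearman_p=float(rho_p),
        n_frames_compared=n,
        proportion_z=float(z),
        proportion_p=float(zp),
        subject_pearson_r=None if pear_r is None else float(pear_r),
        subject_pearson_p=None if pear_p is None else float(pear_p),
        paired_t=None if t_stat is None else float(t_stat),
        paired_p=None if t_p is None else float(t_p),
    )


# ---------------------------------------------------------------------------
# Group comparison (ASD vs non-ASD style tables)


@dataclass(frozen=True)
class GroupStats:
    name: str
    n: int
    mean: float
    se: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[GroupStats, GroupStats]
    t_statistic: float
    p_value: float
    equal_var: bool

    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "name": g.name,
                    "n": g.n,
                    "mean": g.mean,
                    "se": g.se,
                    "ci95": list(g.ci95),
                }
                for g in self.groups
            ],
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "equal_var": self.equal_var,
        }


def compare_groups(
    cohort: pd.DataFrame,
    value_col: str = "social_pct",
    group_col: str = "group",
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample t-test on per-subject scene percentages between groups.

    Student's (equal-variance) t by default, Welch via ``equal_var=False``.
    Reports per-group mean, SE, and t-based 95% CI, mirroring the
    mean (SE) [CI] layout of a clinical comparison table.
    """
    names = sorted(cohort[group_col].unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    samples = {g: cohort.loc[cohort[group_col] == g, value_col].to_numpy(float) for g in names}
    for g, x in samples.items():
        if len(x) < 2:
            raise InsufficientDataError(f"group {g!r} has n={len(x)} < 2")
    stats_out = []
    for g in names:
        x = samples[g]
        n = len(x)
        mean = float(x.mean())
        se = float(x.std(ddof=1) / math.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        stats_out.append(
            GroupStats(g, n, mean, se, (mean - tcrit * se, mean + tcrit * se))
        )
    x1, x2 = samples[names[0]], samples[names[1]]
    if np.array_equal(x1, x2):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(x1, x2, equal_var=equal_var)
    return GroupComparison(
        groups=(stats_out[0], stats_out[1]),
        t_statistic=float(t_stat),
        p_value=float(p),
        equal_var=equal_var,
    )
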