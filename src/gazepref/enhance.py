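"""Image enhancement: CIELab lightness remapping and black-region boosting.

The chain prepares a webcam frame for iris localization and sclera
profiling: the CIELab L channel is contrast-stretched with a gamma of 0.5
(brightening mid-tones so the sclera saturates toward white), and the K
channel of a device-naive CMYK decomposition is stretched with a gamma of 3
(so only genuinely dark regions — the iris and pupil — stay salient).  Both
operations are pixelwise and therefore commute with mirroring.

CIELab conversion assumes sRGB input under the D65 illuminant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab

from .types import validate_rgb


@dataclass(frozen=True)
class EnhanceConfig:
    """Parameters of the intensity remap.

    ``in_range`` is the source intensity window; ``None`` uses the observed
    (min, max) of each input, the default contrast-stretch behavior.  With
    ``percentile_clip`` the window is instead the (1st, 99th) percentile
    span, robust to a few outlier pixels.  ``out_range`` defaults to the
    8-bit gray scale.
    """

    l_gamma: float = 0.5
    k_gamma: float = 3.0
    in_range: tuple[float, float] | None = None
    out_range: tuple[float, float] = (0.0, 255.0)
    percentile_clip: bool = False

    def __post_init__(self) -> None:
        if self.l_gamma <= 0 or self.k_gamma <= 0:
            raise ValueError("gammas must be positive")
        if self.in_range is not None and self.in_range[0] >= self.in_range[1]:
            raise ValueError("in_range low must be < high")
        if self.out_range[0] >= self.out_range[1]:
            raise ValueError("out_range low must be < high")


DEFAULT_CONFIG = EnhanceConfig()


def to_cielab(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an RGB frame to its CIELab channels (L in [0, 100])."""
    frame = validate_rgb(frame)
    lab = rgb2lab(frame)
    return lab[..., 0], lab[..., 1], lab[..., 2]


def _resolve_in_range(
    channel: np.ndarray, config: EnhanceConfig
) -> tuple[float, float]:
    if config.in_range is not None:
        return config.in_range
    if config.percentile_clip:
        lo, hi = np.percentile(channel, [1, 99])
    else:
        lo, hi = float(channel.min()), float(channel.max())
    if lo >= hi:  # constant channel: degenerate window
        raise ValueError(
            f"degenerate intensity range ({lo}, {hi}); supply in_range explicitly"
        )
    return float(lo), float(hi)


def remap_intensity(
    channel: np.ndarray, config: EnhanceConfig, gamma: float | None = None
) -> np.ndarray:
    """Gamma-shaped range remap: v -> out_lo + span * ((v - in_lo)/(in_hi - in_lo))**gamma.

    Values outside ``in_range`` are clipped first; the remap is monotone and
    maps the in_range endpoints exactly onto the out_range endpoints.
    """
    channel = np.asarray(channel, dtype=float)
    gamma = config.l_gamma if gamma is None else gamma
    in_lo, in_hi = _resolve_in_range(channel, config)
    out_lo, out_hi = config.out_range
    t = np.clip((channel - in_lo) / (in_hi - in_lo), 0.0, 1.0)
    return out_lo + (out_hi - out_lo) * t**gamma


def enhanced_lightness(frame: np.ndarray, config: EnhanceConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The contrast-remapped L channel (gamma 0.5 by default, 0-255)."""
    L, _, _ = to_cielab(frame)
    return remap_intensity(L, config, gamma=config.l_gamma)


def k_channel(frame: np.ndarray) -> np.ndarray:
    """Black component of a device-naive CMYK split: K = 1 - max(R,G,B)/255."""
    frame = validate_rgb(frame)
    return 1.0 - frame.max(axis=2) / 255.0


def black_region_enhance(
    frame: np.ndarray, config: EnhanceConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Brighten dark regions: the K channel remapped with gamma 3.

    Output lives in ``out_range`` and is large exactly where the input is
    dark (iris, pupil), which the iris localizer exploits.
    """
    k = k_channel(frame)
    return remap_intensity(k, config, gamma=config.k_gamma)
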