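import numpy as np
import pytest

from gazepref import (
    EyeRenderSpec,
    GazeLabel,
    SessionSpec,
    iris_offset_for_label,
    render_face,
)
from gazepref.detect import detection_from_truth


@pytest.fixture(scope="session")
def eye_spec() -> EyeRenderSpec:
    return EyeRenderSpec()


def face_for_label(label: GazeLabel, noise_sd: float = 0.0, seed: int = 0):
    """A frontal face whose both irises encode ``label`` (not DISTRACTION)."""
    spec = EyeRenderSpec(noise_sd=noise_sd, seed=seed)
    off = iris_offset_for_label(label, spec)
    spec = EyeRenderSpec(iris_offset=off, noise_sd=noise_sd, seed=seed)
    spec2 = EyeRenderSpec(iris_offset=off, noise_sd=noise_sd, seed=seed + 1)
    return render_face(spec, spec2)


@pytest.fixture(scope="session")
def mixed_labels() -> list[GazeLabel]:
    """A deterministic label sequence covering all four categories."""
    rng = np.random.default_rng(2026)
    return [
        GazeLabel(lab)
        for lab in rng.choice(
            ["LEFT", "RIGHT", "CENTER", "DISTRACTION"], size=60, p=[0.3, 0.3, 0.2, 0.2]
        )
    ]


@pytest.fixture(scope="session")
def clean_session(mixed_labels):
    """Noise-free rendered session: list of (frame, detection, true label)."""
    spec = SessionSpec(true_labels=mixed_labels, noise_sd=0.0, seed=11)
    return [
        (frame, detection_from_truth(truth), label)
        for frame, truth, label in __import__("gazepref").generate_session(spec)
    ]
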