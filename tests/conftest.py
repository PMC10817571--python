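"""Shared fixtures: scaled-down study conditions reused across the suite.

The end-to-end study is expensive, so one session-scoped run at desk scale
(64x64 frames, depth-3 networks, 20 epochs) serves every test that needs a
trained model or its downstream tables.
"""

import numpy as np
import pytest
from hypothesis import settings

from nervetrace.pipeline import RunConfig, Seeds, run_study

settings.register_profile("ci", derandomize=True, max_examples=30)
settings.load_profile("ci")

#: covariate ranges for 64x64 phantom frames (nerve ~10-25 % of the frame)
SMALL_RANGES = {"a": (10.0, 24.0), "b": (7.0, 14.0), "center_jitter": 4.0}
SMALL_HARD = {"b": (6.0, 8.0), "aspect": (2.5, 3.2), "blur_sigma": (2.0, 3.0)}


def small_study_config(**overrides) -> RunConfig:
    base = dict(
        n_images=120,
        frame_size=(64, 64),
        input_size=64,
        covariate_ranges=SMALL_RANGES,
        hard_ranges=SMALL_HARD,
        hard_fraction=0.25,
        depth=3,
        base_channels=8,
        epochs=20,
        batch_size=12,
        learning_rate={"unet": 3e-3, "segnet": 1e-2},
        clip_norm=1.0,
        seeds=Seeds(),
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def study_report():
    """One full scaled-down study: both architectures trained for 20 epochs."""
    return run_study(small_study_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
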