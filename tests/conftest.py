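from pathlib import Path

import numpy as np
import pytest

from multifret.channel_split import ChannelLayout
from multifret.simulator import ScenarioSpec, default_layout, render_acquisition


@pytest.fixture(scope="session")
def quad_layout() -> ChannelLayout:
    return default_layout()


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioSpec:
    """A small zero-noise two-stimulant run: baseline ratio 2.0, ISO step to
    1.6 at t=200 s, IBMX (maximizer) step to 1.0 at t=400 s."""
    return ScenarioSpec(
        n_positions=2,
        frames_per_position=60,
        cells_per_position=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def rendered_dataset(tmp_path_factory, small_scenario):
    """The small scenario rendered to disk once per session."""
    out = tmp_path_factory.mktemp("rendered")
    path, truth = render_acquisition(small_scenario, out)
    return path, truth, small_scenario


@pytest.fixture
def textured_image() -> np.ndarray:
    rng = np.random.default_rng(42)
    return rng.integers(50, 4000, size=(48, 48)).astype(np.uint16)
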