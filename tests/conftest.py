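import numpy as np
import pytest

from ecobode import (
    GreenwoodParams,
    SpiralModel,
    generate_geometry,
    landmark_geometry,
    lookup_spec,
)
from ecobode.tonotopy import greenwood_frequency


@pytest.fixture(scope="session")
def midscala():
    return lookup_spec("HiFocus MidScala")


@pytest.fixture(scope="session")
def spiral_fixture(midscala):
    """Noiseless 1.5-turn spiral with analytic ground truth (16 contacts)."""
    model = SpiralModel()
    landmarks, truth = generate_geometry(model, midscala, seed=0)
    return model, landmarks, truth


@pytest.fixture(scope="session")
def recovered_geometry(spiral_fixture, midscala):
    """Imaging-route axes recovered from the noiseless spiral landmarks."""
    _, landmarks, _ = spiral_fixture
    geo = landmark_geometry(landmarks, midscala)
    params = GreenwoodParams()
    return geo.with_frequencies(
        greenwood_frequency(geo.insertion_depth_mm, params)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
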