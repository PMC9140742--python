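import numpy as np
import pytest

from pupilkit import synth

FIXTURE_SEED = 7
N_FRAMES = 80


@pytest.fixture(scope="session")
def indoor_sequence():
    """Default 80-frame indoor (flash) fixture with ground truth, seed 7."""
    return synth.generate_sequence(
        N_FRAMES, synth.ConstrictionProfile(), synth.EyeSceneParams(mode="indoor", seed=FIXTURE_SEED)
    )


@pytest.fixture(scope="session")
def outdoor_sequence():
    """Default 80-frame outdoor (sunlight) fixture with ground truth, seed 7."""
    return synth.generate_sequence(
        N_FRAMES, synth.ConstrictionProfile(), synth.EyeSceneParams(mode="outdoor", seed=FIXTURE_SEED)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
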