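import numpy as np
import pytest

from thermofall import SceneConfig, simulate_state, sum_series


@pytest.fixture(scope="session")
def scene():
    return SceneConfig()


@pytest.fixture(scope="session")
def sitting_sums(scene):
    """One quiet 160-frame sitting window's sums (seeded)."""
    return sum_series(simulate_state("sitting", 160, scene, seed=101))


@pytest.fixture(scope="session")
def walking_sums(scene):
    """1000 frames of forward/backward walking sums (seeded, spread-out)."""
    return sum_series(simulate_state("move_fb", 1000, scene, seed=77))


@pytest.fixture(scope="session")
def fall_sums(scene):
    """One 160-frame window containing a scripted fall (seeded)."""
    return sum_series(simulate_state("fall", 160, scene, seed=55))
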