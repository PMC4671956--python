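import numpy as np
import pytest

from pocketstates import (
    Ensemble,
    HalogenProbeSpec,
    PocketFixtureConfig,
    WaterSpec,
    gen_pocket_fixture,
)


@pytest.fixture
def pocket_model():
    """Default pocket fixture: open gate, bridge waters, Br probe at the
    canonical near-ideal halogen-bond geometry."""
    config = PocketFixtureConfig(
        width=7.5, gate=5.0, chi1=-60.0,
        waters=(WaterSpec("W1", 2.8, 12.0), WaterSpec("W2", 2.8, 10.0),
                WaterSpec("free", 3.0, 45.0)),
        halogen_probe=HalogenProbeSpec("Br", 3.0, 174.0),
    )
    return gen_pocket_fixture(config)


@pytest.fixture
def pocket_ensemble(pocket_model):
    return Ensemble(models=[pocket_model])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a bounded translation."""
    from scipy.spatial.transform import Rotation

    from pocketstates import RigidTransform
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-10, 10, size=3)
    return RigidTransform(rot, trans)
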