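import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sequences():
    from na_contrast.spin32 import sequence_presets

    return sequence_presets()


@pytest.fixture(scope="session")
def environments():
    from na_contrast.environments import default_environments

    return default_environments()


@pytest.fixture(scope="session")
def default_phantom():
    from na_contrast.phantom import build_phantom, default_phantom_spec

    return build_phantom(default_phantom_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20210714)
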