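import copy

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast, small-world configuration factory for simulator tests."""
    from myoswitch.config import DEFAULTS, _build

    def make(**overrides):
        d = copy.deepcopy(DEFAULTS)
        d["world"].update(nx=20, ny=20)
        d["run"].update(n_founders=8, n_steps=30, record_steps=[10, 30], seed=0)
        for dotted, value in overrides.items():
            section, key = dotted.split(".")
            d[section][key] = value
        return _build(d)

    return make
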