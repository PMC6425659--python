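import pytest
from hypothesis import settings

import carepath as cp

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return cp.default_config(n_persons=800, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return cp.generate_bundle(small_config)
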