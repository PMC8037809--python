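import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def reference_insilico():
    from bbbperm import load_reference_insilico

    return load_reference_insilico()


@pytest.fixture
def reference_descriptors():
    from bbbperm import load_reference_descriptors

    return load_reference_descriptors()


@pytest.fixture
def quiet_build_series():
    """build_series with replicate-count warnings silenced, for terse fixtures."""
    from bbbperm import build_series

    def _build(measurements, **kwargs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return build_series(measurements, **kwargs)

    return _build
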