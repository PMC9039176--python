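import pytest
from hypothesis import HealthCheck, settings

import rtburden as rb
from rtburden.comparative import base_case
from rtburden.synthetic import make_model_tables

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ps():
    return rb.default_parameters()


@pytest.fixture(scope="session")
def tables(ps):
    return make_model_tables(ps)


@pytest.fixture(scope="session")
def base(ps, tables):
    """Base-case aggregate and per-age results (computed once per session)."""
    return base_case(ps, tables=tables)
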