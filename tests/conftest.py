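import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from duplexlb import (  # noqa: E402
    default_background_variants,
    default_reference,
    default_spike_ins,
)
from duplexlb.pipeline import RunConfig, run_pipeline  # noqa: E402


@pytest.fixture(scope="session")
def demo_ref():
    return default_reference()


@pytest.fixture(scope="session")
def spike_ins(demo_ref):
    return default_spike_ins(demo_ref)


@pytest.fixture(scope="session")
def background(demo_ref):
    return default_background_variants(demo_ref)


@pytest.fixture(scope="session")
def default_run():
    """Full validation-series pipeline run at default study conditions.

    Shared by the end-to-end tests; this is the expensive fixture (a few
    minutes), computed once per session.
    """
    return run_pipeline(RunConfig(seed=42))
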