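import pytest
from hypothesis import HealthCheck, settings

from pirma import (
    build_panel_table,
    default_config,
    generate_registry,
    make_fixture_from_counts,
    reference_panel_counts,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published_counts():
    """Published per-(arm, month) evaluation and worsening counts."""
    return reference_panel_counts()


@pytest.fixture(scope="session")
def published_registry(published_counts):
    """Deterministic registry reproducing the published summary counts."""
    return make_fixture_from_counts(published_counts)


@pytest.fixture(scope="session")
def published_panels(published_registry):
    """(panel_table, observations) built from the published-counts registry."""
    return build_panel_table(published_registry)


@pytest.fixture(scope="session")
def small_registry():
    """A small default-condition synthetic registry."""
    return generate_registry(default_config(n_patients=800), seed=1)
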