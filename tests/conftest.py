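import hypothesis
import pytest

from fecolumn import (
    ColumnSpec,
    column_hydraulics,
    make_scenario,
    simulate_column,
)

hypothesis.settings.register_profile(
    "fecolumn", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("fecolumn")


@pytest.fixture(scope="session")
def default_spec():
    return ColumnSpec()


@pytest.fixture(scope="session")
def default_hydraulics(default_spec):
    return column_hydraulics(default_spec)


@pytest.fixture(scope="session")
def treatment_run():
    """Full 43-day inoculated-column run with shipped defaults (noise-free)."""
    return simulate_column(make_scenario("treatment"))


@pytest.fixture(scope="session")
def control_run():
    """Full 43-day sterile-control run with shipped defaults (noise-free)."""
    return simulate_column(make_scenario("control"))


@pytest.fixture(scope="session")
def tracer_run():
    return simulate_column(
        make_scenario("tracer", duration=40.0, sampling_days=(40.0,))
    )
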