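import pytest

from netpharm.pipeline import simulate_fixture
from netpharm.simulate import SimulationSpec


@pytest.fixture(scope="session")
def default_spec() -> SimulationSpec:
    """The documented default study conditions, seeded."""
    return SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_spec):
    """A complete synthetic input directory with planted ground truth."""
    return simulate_fixture(default_spec, tmp_path_factory.mktemp("fixture"))
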