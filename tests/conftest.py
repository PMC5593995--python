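import pytest

from mipscsf.fixtures import load_fixture_tables
from mipscsf.schedule import InjectionSchedule
from mipscsf.synthetic import PhantomSpec


@pytest.fixture(scope="session")
def schedule():
    return InjectionSchedule.default_protocol()


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Desk-scale phantom grid for fast segmentation tests."""
    return PhantomSpec(
        grid_shape=(48, 48, 32),
        spacing=(1.0, 1.0, 1.164),
        brain_semi_axes_mm=(21.0, 20.0, 15.0),
        seed=7,
    )
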