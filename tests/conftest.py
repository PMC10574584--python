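import pytest

from assayunc import run_gum
from assayunc.synthetic import study_fixture


@pytest.fixture(scope="session")
def fixture():
    """The packaged AP/4HA study fixture (deterministic build)."""
    return study_fixture()


@pytest.fixture(scope="session")
def gum_results(fixture):
    return run_gum(fixture.config, fixture.calibration, fixture.qc_levels())
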