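import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pahscreen.reference_data import COMPOUND_ORDER, SampleRecord

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_sample(sample_id="S1", default=0.0, **conc) -> SampleRecord:
    """Sample with every compound at ``default`` except the given overrides."""
    concentrations = {abbr: default for abbr in COMPOUND_ORDER}
    concentrations.update(conc)
    return SampleRecord(sample_id, concentrations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sample(rng):
    conc = {abbr: float(c) for abbr, c in
            zip(COMPOUND_ORDER, rng.lognormal(4.0, 1.0, len(COMPOUND_ORDER)))}
    return SampleRecord("R1", conc)
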