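import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zfbmd import PipelineConfig, SimulationDesign, simulate_plates
from zfbmd.preprocess import DoseGroup, DoseResponseSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def config():
    return PipelineConfig(seed=1)


@pytest.fixture
def design():
    """The reference screening condition: quantal-linear truth, 32 wells/group."""
    return SimulationDesign(
        doses=(0.0, 1.5, 6.0, 25.0, 50.0),
        theta_true=(0.05, 0.05),
        mortality_rate_24h=0.0,
        seed=7,
    )


@pytest.fixture
def records(design):
    return simulate_plates(design)


def make_series(d, f, n=32, substance="CHEM-X", endpoint="EDEM", kind="chemical"):
    """Series with given dose/fraction vectors and a common group size."""
    groups = tuple(
        DoseGroup(d=float(di), n=int(n), y=int(round(fi * n)))
        for di, fi in zip(d, f)
    )
    return DoseResponseSeries(
        substance_id=substance, endpoint=endpoint, groups=groups,
        substance_kind=kind,
    )


@pytest.fixture
def monotone_series():
    return make_series([0, 1, 5, 10, 20], [0.0, 0.125, 0.25, 0.5, 0.75])
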