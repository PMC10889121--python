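import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppgrid.grid import Segmentation
from ppgrid.simulate import SimulationConfig, generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """30/35 eyes, two segmentations, tilted 7 deg - cheap shared cohort."""
    cfg = SimulationConfig(
        n_control=30,
        n_glaucoma=35,
        seed=123,
        segmentations=(Segmentation.RNFL, Segmentation.ORL),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tilt0_cohort():
    cfg = SimulationConfig(
        n_control=30,
        n_glaucoma=35,
        tilt_deg=0.0,
        seed=123,
        segmentations=(Segmentation.RNFL,),
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
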