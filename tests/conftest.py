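import numpy as np
import pytest

from vtgrs.cohort_model import MarkerDef
from vtgrs.synthetic_cohort import default_config, simulate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """One marginal-mode cohort at the published study conditions."""
    return simulate_cohort(default_config(seed=20230906))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_markers():
    return [
        MarkerDef("rs1", "A", "G"),
        MarkerDef("rs2", "T", "C", protective=True),
        MarkerDef("rs3", "C", "DEL"),
    ]
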