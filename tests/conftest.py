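import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gelsolv as g

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return g.default_group_table()


@pytest.fixture(scope="session")
def sul():
    return g.sulindac_composition()


@pytest.fixture(scope="session")
def meg():
    return g.meglumine_composition()


@pytest.fixture()
def linear_dataset():
    """Noiseless A_L diagram: K = 1.5/mM, S0 = 0.04 mM, 8 doubling points."""
    lt = 6.25 / 2.0 ** np.arange(7, -1, -1)
    return g.PhaseSolubilityDataset(
        ligand_total=lt,
        drug_total=g.predict_total_solubility(1.5, 0.04, lt),
        intrinsic_solubility=0.04,
    )


@pytest.fixture()
def sink():
    return g.sink_protocol()
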