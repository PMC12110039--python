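import numpy as np
import pandas as pd
import pytest

from spatialtme import synthetic
from spatialtme.panel import builtin_signature


@pytest.fixture(scope="session")
def signature():
    return builtin_signature()


@pytest.fixture(scope="session")
def cohort():
    return synthetic.generate_cohort(12, 8, seed=1)


@pytest.fixture(scope="session")
def design():
    return synthetic.default_design()


@pytest.fixture(scope="session")
def synthetic_counts(cohort, design):
    """Default-design synthetic dataset shared across tests."""
    return synthetic.generate_aoi_counts(cohort, design, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_counts():
    """4 genes x 2 AOIs with Q3s of 50 and 200 over positive counts."""
    return pd.DataFrame(
        {
            "A1": [10.0, 20.0, 50.0, 50.0],
            "A2": [40.0, 80.0, 200.0, 200.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
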