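import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from soilrisk.reference import load_reference_tables
from soilrisk.surveys import Survey

# Published survey-mean concentrations (mg/kg) used as the reference input
MEAN_CONC = {"As": 9.08, "Cd": 0.36, "Cr": 73.06, "Hg": 0.13, "Pb": 28.14}


@pytest.fixture(scope="session")
def tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def mean_conc():
    return dict(MEAN_CONC)


@pytest.fixture()
def toy_survey():
    """Three hand-checkable samples spanning three pH classes."""
    df = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "pH": [5.0, 6.0, 7.0],
            "As": [2.0, 10.0, 30.0],
            "Cd": [0.5, 0.2, 0.7],
            "Cr": [50.0, 80.0, 120.0],
            "Hg": [0.05, 0.12, 0.7],
            "Pb": [20.0, 30.0, 150.0],
        }
    )
    return Survey(df, provenance="toy")


@pytest.fixture()
def rng():
    return np.random.default_rng(20170740)
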