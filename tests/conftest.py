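import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stresstypo.schema import CohortTable, VariableSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def tiny_schema():
    return [
        VariableSpec("smoking", "ordinal", ("never", "former", "current")),
        VariableSpec("job", "nominal", ("blue", "white")),
        VariableSpec("glucose", "numeric", units="mg/dL", plausible_range=(40, 500)),
        VariableSpec("stress", "numeric"),
    ]


@pytest.fixture
def tiny_cohort(tiny_schema):
    data = pd.DataFrame(
        {
            "smoking": ["never", "former", "current"],
            "job": ["blue", "white", "white"],
            "glucose": [90.0, 105.0, 88.0],
            "stress": [1.0, 4.0, 2.5],
        }
    )
    return CohortTable(schema=tiny_schema, data=data)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
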