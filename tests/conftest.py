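import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bmdpotency as bp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_data_adjustment_warnings():
    """Half-count adjustments are expected throughout the simulated data."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="replaced .* zero response")
        yield


@pytest.fixture(scope="session")
def two_compound_cluster():
    """A responsive compound and a no-effect compound, fitted jointly.

    Mirrors the basic covariate setting: the responsive compound pins the
    shared shape; the null compound has background-only response.
    """
    design = bp.StudyDesign(doses=(0, 1, 2, 4, 8, 16), treated_replicates=2,
                            control_replicates=4)
    truth = {
        "hot": bp.ExponentialParams(a=1.0, b=0.2, c=3.0, d=1.0),
        "null": bp.ExponentialParams(a=1.5, b=0.0, c=3.0, d=1.0),
    }
    datasets = bp.simulate_continuous_mn(design, truth, noise_gsd=1.2, seed=0)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="replaced .* zero response")
        model = bp.ExponentialClusterModel(random_state=0).fit(datasets)
    return model, datasets, truth


@pytest.fixture(scope="session")
def quantal_cluster():
    truth = {
        "q1": bp.QuantalParams(a=0.05, b=150.0, c=2.0),
        "q2": bp.QuantalParams(a=0.10, b=30.0, c=2.0),
    }
    design = bp.StudyDesign(doses=(0, 10, 30, 100, 300))
    datasets = bp.simulate_quantal_cancer(design, truth, seed=3)
    model = bp.LogLogisticClusterModel(random_state=0).fit(datasets)
    return model, datasets, truth
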