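import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import covkin as ck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def conditions():
    """Default fluorogenic assay: S=20 µM, Km=17.4 µM, E0=0.42 nM, 40 min."""
    return ck.AssayConditions()


@pytest.fixture(scope="session")
def slow_curves(conditions):
    """Noiseless slow-binding set (azadipeptide-nitrile-like ground truth)."""
    return ck.simulate_progress_curves(
        ck.GU1303_LIKE, conditions, ck.DEFAULT_SLOW_GRID_NM)


@pytest.fixture(scope="session")
def tight_curves(conditions):
    """Noiseless fast/tight-binding set (Ki = 0.013 nM ground truth)."""
    return ck.simulate_progress_curves(
        ck.GU2602_LIKE, conditions, ck.DEFAULT_TIGHT_GRID_NM)


@pytest.fixture(scope="session")
def full_scale_signal(conditions):
    """Final signal of an uninhibited run (the assay's full-scale reading)."""
    base = ck.simulate_progress_curves(ck.GU1303_LIKE, conditions, [0.0])
    return float(np.max(base[0].signal))
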