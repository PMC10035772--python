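import numpy as np
import pytest

import pulsescape as ps

SCHEDULE_S = np.array([60.0 * m for m in ps.PULSE_ESCAPE_SCHEDULE_MIN])


@pytest.fixture(scope="session")
def rates():
    return ps.TIBIAL_NERVE_RATES


@pytest.fixture(scope="session")
def motility():
    return ps.DEFAULT_MOTILITY


@pytest.fixture(scope="session")
def geom():
    return ps.DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def schedule_s():
    return SCHEDULE_S.copy()


@pytest.fixture(scope="session")
def model_curve(rates, motility, geom):
    """Noiseless grid-solver decay at the imaging schedule plus 600 min."""
    cfg = ps.SimulationConfig(
        sample_times=tuple(SCHEDULE_S) + (36_000.0,), duration=36_000.0, solver="grid"
    )
    return ps.expected_decay(rates, motility, geom, cfg)


@pytest.fixture(scope="session")
def reference_curve(model_curve):
    """The model decay as the preprocessing stage would deliver it:
    time origin at the 1-min frame, normalised there."""
    values = model_curve.values[:11] / model_curve.values[0]
    return ps.DecayCurve(SCHEDULE_S - 60.0, values)


@pytest.fixture(scope="session")
def reference_fit(reference_curve):
    return ps.fit_double_exponential(reference_curve)
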