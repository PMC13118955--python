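import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# below-detection warnings from control wells are expected in many tests
logging.getLogger("mesofluor").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_experiment():
    """One default-condition simulated experiment (compact, 1/3/6/9 μg/mL)."""
    from mesofluor import simgen

    return simgen.generate_dose_response_experiment(
        simgen.DEFAULT_CONCENTRATIONS, "compact",
        simgen.OpticsParams(), simgen.NoiseParams(), seed=20240917,
    )


@pytest.fixture
def analyzed_default(default_experiment):
    from mesofluor import pipeline

    b = default_experiment
    return b, pipeline.analyze_frames(
        b.all_frames(), b.calibration, b.concentration_map(), roles=b.role_map()
    )
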