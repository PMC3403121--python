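import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import tempoblocks as tb


@pytest.fixture(scope="session")
def planted():
    """Default noise-free planted design (10 x 15, five 5 x 4 blocks)."""
    design = tb.default_design(seed=1)
    matrix, truth = tb.generate_block_matrix(design)
    return matrix, truth


@pytest.fixture(scope="session")
def phase_series():
    """One phase-structured series (6 phases x 3 points, turnover 0.5)."""
    return tb.generate_phase_series(seed=0)
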