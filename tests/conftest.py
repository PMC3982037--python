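import json
from pathlib import Path

import pytest

from mmrd import KineticParams, make_uniform_grid

DATA_DIR = Path(__file__).parent / "data"

#: The case-study parameter grid: 3 saturation x 7 reaction-diffusion values.
CASE_ALPHAS = (0.1, 1.0, 1.5)
CASE_KS = (0.1, 1.0, 5.0, 10.0, 20.0, 50.0, 100.0)
CASE_GRID = [(k, a) for a in CASE_ALPHAS for k in CASE_KS]


@pytest.fixture(scope="session")
def unit_params():
    """k=1, alpha=0.1, bulk mediator at both faces."""
    return KineticParams(k=1.0, alpha=0.1)


@pytest.fixture(scope="session")
def grid101():
    return make_uniform_grid(101)


@pytest.fixture(scope="session")
def regression_fixture():
    """Frozen max-abs PM-vs-FD discrepancies for the 21 case-study cases."""
    return json.loads((DATA_DIR / "sweep_regression.json").read_text())
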