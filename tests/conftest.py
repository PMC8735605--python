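import numpy as np
import pytest

from dosefit import BeamModelParams, load_fixture

ENERGIES = ("4 MV", "6 MV", "10 MV", "18 MV")


@pytest.fixture(scope="session")
def beam_params() -> dict:
    """Reference (n, mu) per energy from the packaged dataset."""
    return load_fixture("table2")


@pytest.fixture(scope="session")
def params_6mv(beam_params) -> BeamModelParams:
    return beam_params["6 MV"]


def brute_force_dmax(n: float, mu: float, step: float = 1e-4) -> float:
    """Independent arg-max of the buildup-tail product on a dense grid."""
    grid = np.arange(step, 2.0 * np.sqrt(n) + step, step)
    y = grid / (grid * grid + n) * np.exp(-mu * grid)
    return float(grid[np.argmax(y)])
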