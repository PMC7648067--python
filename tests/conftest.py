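import numpy as np
import pytest

from condensate_proximity.calibration import FunctionCurve, build_curve
from condensate_proximity.synthetic_data import (
    TetramerEquilibrium,
    default_concentration_grid,
    generate_calibration_table,
    tetramer_signal,
)


@pytest.fixture(scope="session")
def eq() -> TetramerEquilibrium:
    """Default reporter equilibrium used across tests."""
    return TetramerEquilibrium()


@pytest.fixture(scope="session")
def exact_curve(eq):
    """The reporter I(c) evaluated analytically (no interpolation error)."""
    return FunctionCurve(lambda c: float(tetramer_signal(eq, c)), c_min=1.0, c_max=50.0)


@pytest.fixture(scope="session")
def interp_curve(eq):
    """Reporter curve interpolated through a noiseless 16-point table."""
    table = generate_calibration_table(eq, default_concentration_grid(), noise_cv=0.0)
    return build_curve(table, isotonic=False)


@pytest.fixture(scope="session")
def anchored_curve():
    """Tetramer-surrogate curve rescaled so the grid point at 4.87 uM reads 818 a.u."""
    base = TetramerEquilibrium(brightness=1.0)
    scale = 818.0 / float(tetramer_signal(base, 4.87))
    eq = TetramerEquilibrium(brightness=scale)
    grid = np.unique(np.concatenate([default_concentration_grid(), [4.87]]))
    table = generate_calibration_table(eq, grid, noise_cv=0.0)
    return build_curve(table, isotonic=False)
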