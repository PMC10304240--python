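import numpy as np
import pytest

from mitolens.bilayer import reference_wall
from mitolens.geometry import build_mitochondrion
from mitolens.transport import SourceGrid, trace


@pytest.fixture(scope="session")
def wall():
    return reference_wall()


@pytest.fixture(scope="session")
def default_model(wall):
    """The standard lens-mitochondrion model: R=1 um, a=400 nm,
    n_A=1.33, n_B=1.48, 25-medium wall."""
    return build_mitochondrion(wall_stack=wall)


@pytest.fixture(scope="session")
def null_model():
    return build_mitochondrion(n_A=1.33, n_B=1.33, wall_stack=None)


@pytest.fixture(scope="session")
def small_trace(default_model):
    """A modest deterministic trace of the default model (shared by
    several tests to amortise the cost)."""
    grid = SourceGrid(spacing=40.0, wavelength=550.0)
    records, ledger = trace(default_model, grid, strategy="ii", epsilon=1e-9)
    return records, ledger


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
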