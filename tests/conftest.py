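import numpy as np
import pytest

from funcforest.curves import DoseGrid, ResponseCurve


@pytest.fixture
def eight_dose_grid() -> DoseGrid:
    """CCLE-style 8-point grid from 0.0025 to 8 uM (log-spaced)."""
    return DoseGrid(np.logspace(np.log10(0.0025), np.log10(8.0), 8))


@pytest.fixture
def make_curve(eight_dose_grid):
    def _make(values, grid=None, sample_id=None):
        return ResponseCurve(grid=grid or eight_dose_grid,
                             values=np.asarray(values, dtype=float),
                             sample_id=sample_id)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
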