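import numpy as np
import pytest

from fusionscope import AcquisitionSpec, FieldSpec, StateGrid


@pytest.fixture
def noiseless_spec():
    """Small noiseless field so segmentation can be checked exactly."""
    return FieldSpec(n_cells=16, noise_sd=0.0, seed=7)


@pytest.fixture
def acq():
    return AcquisitionSpec()


@pytest.fixture
def grid():
    return StateGrid()


@pytest.fixture
def coarse_grid():
    """Coarse grid (and no start-frame filter) for fast likelihood tests."""
    return StateGrid(d_values=np.geomspace(1e-2, 1e2, 12), infer_start_frame=0)
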