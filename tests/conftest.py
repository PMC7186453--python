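import numpy as np
import pytest

import tdcsmap as tm


@pytest.fixture(scope="session")
def grid():
    """Desk-scale phantom grid with EPI-like voxels."""
    return tm.VoxelGrid(shape=(16, 16, 8), spacing=(3.4, 3.4, 5.0))


@pytest.fixture(scope="session")
def phantom(grid):
    """Straight-wire phantom: (CurrentPath, simulated FieldMap)."""
    return tm.phantom_fixture(grid)


@pytest.fixture(scope="session")
def waveform():
    """Two-scan block design with the phantom current levels (80 volumes)."""
    return tm.make_waveform(
        [0.0, 0.5, 1.0, 1.5],
        order=3,
        block_length=40.0,
        tr=4.0,
        n_scans=2,
        scan_length=160.0,
    )


@pytest.fixture(scope="session")
def noisefree_series(phantom, waveform):
    _, field = phantom
    return tm.simulate_series(field, waveform, tm.AcquisitionParams(tr=4.0, seed=1))


@pytest.fixture(scope="session")
def noisy_series(phantom, waveform):
    """Phantom series at complex SNR 50."""
    _, field = phantom
    params = tm.AcquisitionParams(tr=4.0, complex_noise_sd=2.0, seed=2)
    return tm.simulate_series(field, waveform, params)


def make_field_map(values, spacing=(1.0, 1.0, 1.0), mask=None):
    """Wrap an array (any shape up to 3D) into a FieldMap on a unit grid."""
    values = np.asarray(values, dtype=float)
    while values.ndim < 3:
        values = values[..., None]
    g = tm.VoxelGrid(shape=values.shape, spacing=spacing)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return tm.FieldMap(grid=g, values=values, mask=mask)
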