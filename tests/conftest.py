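import numpy as np
import pytest

from pmdti.dwi_io import GradientTable, generate_directions
from pmdti.phantom import (build_gray_white_slab, build_specimen_phantom,
                           simulate_dwi)


@pytest.fixture(scope="session")
def phantom32():
    return build_specimen_phantom((32, 32, 32), seed=1)


@pytest.fixture(scope="session")
def gtab6():
    dirs = generate_directions(6, seed=2)
    return GradientTable(bvals=np.r_[0.0, [4500.0] * 6],
                         bvecs=np.vstack([np.zeros((1, 3)), dirs]))


@pytest.fixture(scope="session")
def gtab12():
    dirs = generate_directions(12, seed=2)
    return GradientTable(bvals=np.r_[0.0, 0.0, [4500.0] * 12],
                         bvecs=np.vstack([np.zeros((2, 3)), dirs]))


@pytest.fixture(scope="session")
def series32(phantom32, gtab6):
    return simulate_dwi(phantom32, gtab6, repeats=3)


@pytest.fixture(scope="session")
def gw_fixture():
    """Gray--white boundary phantom with its simulated acquisition."""
    ph = build_gray_white_slab()
    dirs = generate_directions(12, seed=2)
    gtab = GradientTable(bvals=np.r_[0.0, 0.0, [4500.0] * 12],
                         bvecs=np.vstack([np.zeros((2, 3)), dirs]))
    return ph, simulate_dwi(ph, gtab, repeats=1)
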