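import numpy as np
import pytest

from chmet import PhantomSpec, generate_psoct_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A modest vessel-rich phantom with default study-level parameters."""
    spec = PhantomSpec(n_alines=128, n_bscans=32, n_depth=220, seed=2)
    vol, truth = generate_psoct_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def uniform_noiseless_phantom():
    """No depolarization anywhere, no detector noise: the DOPU=1 limit."""
    spec = PhantomSpec(
        n_alines=96, n_bscans=16, n_depth=200, melanin_p=0.0, rpe_mixing=0.0,
        snr_db=np.inf, vessels=(), seed=3,
    )
    vol, truth = generate_psoct_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def random_state_phantom():
    """Every stroma and RPE voxel gets an i.i.d. random Poincare state."""
    spec = PhantomSpec(
        n_alines=128, n_bscans=24, n_depth=220, choroid_um=300.0,
        melanin_p=1.0, rpe_mixing=1.0, snr_db=np.inf, vessels=(), seed=4,
    )
    vol, truth = generate_psoct_phantom(spec)
    return spec, vol, truth
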