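import numpy as np
import pytest

import fgflim as fg

BIN_WIDTH_PS = 12500.0 / 256.0   # 12.5 ns window, 256 bins


@pytest.fixture(scope="session")
def irf_default() -> fg.IRFKernel:
    """Gaussian 100 ps IRF on the default 256-bin / 12.5 ns grid."""
    return fg.make_irf()


@pytest.fixture(scope="session")
def irf_delta() -> fg.IRFKernel:
    """Single-bin response at 1250 ps on the default grid."""
    return fg.delta_irf(BIN_WIDTH_PS, 256, center=1250.0)


@pytest.fixture(scope="session")
def fg_params() -> fg.DecayModelParams:
    return fg.fg_decay_params()


@pytest.fixture(scope="session")
def bg_params() -> fg.DecayModelParams:
    return fg.background_decay_params()


@pytest.fixture
def acq():
    """Acquisition-settings factory with the standard photon budget."""
    def _make(seed=0, total_photons=1_000_000, n_bins=256, period_ns=12.5):
        return fg.AcquisitionSettings(n_bins, period_ns, total_photons, seed)
    return _make
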