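import numpy as np
import pytest

import cyclect as cc


@pytest.fixture(scope="session")
def sim_small():
    """8 low-dose + matching reference slices at 32x32 (5% dose)."""
    low, ref = cc.simulate_slices(8, size=32, dose_fraction=0.05, seed=0,
                                  n_angles=60, incident_counts=1.5e4,
                                  return_reference=True)
    return low, ref


@pytest.fixture(scope="session")
def disk_pair():
    """A clean binary disk and a noisy version (white Gaussian, sigma=100)."""
    rng = np.random.default_rng(7)
    yy, xx = np.mgrid[0:64, 0:64]
    clean = 1000.0 * (((yy - 32) ** 2 + (xx - 32) ** 2) < 400)
    return clean, clean + rng.normal(0, 100, clean.shape)
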