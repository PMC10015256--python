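import numpy as np
import pytest

from mefc.synthetic import make_phantom_anatomy, simulate_session
from mefc.types import AcquisitionSpec, BoldSeries, default_affine


@pytest.fixture(scope="session")
def small_anatomy():
    """12x12x6 phantom, 8 ROIs (2 subcortical), 4 latent networks."""
    return make_phantom_anatomy((12, 12, 6), 8, seed=1,
                                n_subcortical=2, n_networks=4)


@pytest.fixture(scope="session")
def short_mbme_acq():
    return AcquisitionSpec(tr_ms=900.0, te_ms=(11.0, 30.0, 49.0), n_volumes=120)


@pytest.fixture(scope="session")
def noiseless_mbme(small_anatomy, short_mbme_acq):
    """Pure mono-exponential echoes: no BOLD, noise, drift or physio."""
    me, motion = simulate_session(
        small_anatomy, short_mbme_acq, bold_amplitude=0.0, seed=5,
        noise_sd=0.0, include_drift=False, include_physio=False)
    return me, motion


def random_bold(shape, n_volumes, seed, tr_ms=900.0, mask=None):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal(shape + (n_volumes,))
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return BoldSeries(data=data, tr_ms=tr_ms, mask=mask,
                      affine=default_affine())
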