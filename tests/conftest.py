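import numpy as np
import pytest

from discqmri import synthetic as syn
from discqmri.relaxometry import FitConfig, fit_map


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort: 133 subjects, 650 disc records."""
    return syn.generate_cohort(seed=20230101)


@pytest.fixture(scope="session")
def noiseless_phantom_map():
    """Zero-noise phantom and its fitted T1rho map."""
    spec = syn.PhantomSpec(snr=np.inf)
    phantom = syn.generate_phantom(spec, seed=1)
    rmap = fit_map(phantom.t1rho_series, config=FitConfig(noise_sigma=1.0))
    return phantom, rmap


@pytest.fixture(scope="session")
def snr50_phantom_map():
    """Default phantom at SNR 50 (seed 7) and its fitted T1rho map."""
    spec = syn.PhantomSpec()
    phantom = syn.generate_phantom(spec, seed=7)
    rmap = fit_map(phantom.t1rho_series, config=FitConfig(noise_sigma=spec.sigma))
    return phantom, rmap
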