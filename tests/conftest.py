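import warnings

import pytest

from alknma import NmaModelSpec, load_fixture
from alknma.nma import fit_nma

# arviz emits a refactor FutureWarning on import; irrelevant to the tests
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def fast_spec():
    """Short sampler runs for unit tests; defaults stay for acceptance."""
    return NmaModelSpec(chains=2, burn_in=500, kept_iterations=3000, thin=2, seed=11)


@pytest.fixture(scope="session")
def pfs_network():
    return load_fixture("pfs")


@pytest.fixture(scope="session")
def pfs_fast_fit(pfs_network, fast_spec):
    return fit_nma(pfs_network, fast_spec, check_convergence=False)
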