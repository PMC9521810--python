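import numpy as np
import pytest

from itcmix.models import TitrationProtocol
from itcmix.probability import PriorSpec
from itcmix.simulate import SimulationDesign, default_truth, simulate_experiment


@pytest.fixture
def protocol():
    return TitrationProtocol(np.full(24, 12e-6))


@pytest.fixture
def truth():
    return default_truth()


@pytest.fixture
def em_dataset(protocol):
    """One low-noise simulated EM titration with its realized truth."""
    design = SimulationDesign(n_replicates=1, seed=123, protocol=protocol)
    return simulate_experiment(design, 0)


@pytest.fixture
def lognormal_priors():
    return PriorSpec(r0_prior="lognormal", ls_prior="lognormal")
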