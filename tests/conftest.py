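import numpy as np
import pytest

from stpfit import QuantalGroundTruth, builtin_params


@pytest.fixture(scope="session")
def sh_params():
    """Septohippocampal PV projection synapse model (population means)."""
    return builtin_params("SH")


@pytest.fixture(scope="session")
def hc_params():
    """Local hippocampal PV synapse model (population means)."""
    return builtin_params("HC")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def sh_ground_truth():
    """Quantal ground truth matching the SH population estimates."""
    return QuantalGroundTruth(n_sites=15, q_pa=36.4)
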