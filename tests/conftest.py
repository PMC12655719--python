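import numpy as np
import pytest

from dooit.data_io import ComponentDescriptors
from dooit.synthetic import SyntheticSpec, gen_qspr_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def components():
    """A solute and two solvent components, with sigma curves."""
    def curve(scale):
        return tuple(scale * (k - 30) / 30.0 for k in range(61))

    return {
        "API": ComponentDescriptors("API", -12.0, -3.0, -5.0, -4.0, -6.5, curve(2.0)),
        "water": ComponentDescriptors("water", -8.0, -2.0, -4.5, -1.5, -2.0, curve(1.0)),
        "dmso": ComponentDescriptors("dmso", -10.0, -1.0, -2.0, -4.0, -4.0, curve(-1.0)),
    }


@pytest.fixture(scope="session")
def small_qspr():
    """A small planted table shared by the slower model-search tests."""
    spec = SyntheticSpec(n_samples=120, n_informative=3, n_noise=3,
                         n_solutes=4, seed=11)
    return gen_qspr_table(spec)
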