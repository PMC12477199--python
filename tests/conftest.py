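import numpy as np
import pytest

from vola.quantify import semi_quantify
from vola.synth import SynthConfig, generate_dataset
from vola.tables import fill_missing_half_min


@pytest.fixture(scope="session")
def default_ds():
    """The default strong-separation synthetic study, seed 17."""
    return generate_dataset(SynthConfig(seed=17))


@pytest.fixture(scope="session")
def default_ct(default_ds):
    """Semi-quantified, half-minimum-filled concentration table."""
    return fill_missing_half_min(
        semi_quantify(default_ds.features, default_ds.is_params))


@pytest.fixture(scope="session")
def small_cfg():
    """A fast 60-compound configuration for Monte-Carlo style tests."""
    return SynthConfig(n_compounds=60, n_key_up=3, n_key_down=2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
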