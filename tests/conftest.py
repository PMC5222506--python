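import numpy as np
import pytest

from coneflow.synthetic import SyntheticMosaicConfig


@pytest.fixture
def perfect_lattice_config():
    """Disorder-free triangular mosaic filling the default 200x200 ROI."""
    return SyntheticMosaicConfig(jitter_sd_frac=0.0, dropout_frac=0.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
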