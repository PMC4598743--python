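import numpy as np
import pytest

from sdmclust.synth import CellSpec, generate_cell


@pytest.fixture
def three_level_cell():
    """Noise-free piecewise-constant cell: L* exactly {25, 60, 90}."""
    spec = CellSpec(noise_sd=0.0, chromatin_density=0.0,
                    L_nucleus=25.0, L_cytoplasm=60.0, L_background=90.0)
    return generate_cell(spec)


@pytest.fixture
def noisy_cell():
    spec = CellSpec(noise_sd=1.5, chromatin_density=0.15, chromatin_contrast=-15.0,
                    L_nucleus=35.0, L_cytoplasm=60.0, L_background=90.0, seed=7)
    return generate_cell(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
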