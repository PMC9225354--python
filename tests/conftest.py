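import numpy as np
import pytest

from imatct import PhantomSpec, generate_ct_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced leg phantom (10% fat, 30 HU noise) shared across tests."""
    spec = PhantomSpec(
        shape_vox=(32, 160, 160),
        fat_fraction=0.10,
        hu_noise_sd=30.0,
        rng_seed=11,
    )
    vol, truth = generate_ct_phantom(spec)
    return spec, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
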