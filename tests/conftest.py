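import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Model whose stage-3 resolution is 16x32x32 (the scaled-down study size)."""
    from volgan.networks import ModelConfig
    return ModelConfig(grid=(64, 128, 128), c_gen=8, c_critic=8)


@pytest.fixture(scope="session")
def tiny_stacks():
    """24 noiseless-ish phantoms at 16x32x32 with varied densities."""
    from volgan.phantoms import PhantomSpec, generate_phantom
    rng = np.random.default_rng(7)
    vols = []
    for i in range(24):
        spec = PhantomSpec(
            axial_slices=16, vertical_extent=32, horizontal_extent=32,
            cortical_thickness=2.5,
            cortical_intensity=float(rng.uniform(0.6, 0.9)),
            trabecular_fill=float(rng.uniform(0.2, 0.5)),
            noise_sd=0.02, seed=i)
        vols.append(generate_phantom(spec).data)
    return np.stack(vols)
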