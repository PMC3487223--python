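import numpy as np
import pytest

from dopamet.simulate import SimulationConfig


@pytest.fixture
def clean_config():
    """Small noiseless, distortion-free design: every spot's log2 ratio equals
    the gene's true effect exactly."""
    return SimulationConfig(
        n_genes=40,
        frac_regulated=0.25,
        effect_log2_mean=1.0,
        effect_log2_sd=0.0,
        noise_sd=0.0,
        pool_bio_sd=0.0,
        distortion_rotation_max_deg=0.0,
        distortion_scale_range=(1.0, 1.0),
        distortion_translation_max=0.0,
        rng_seed=42,
    )


@pytest.fixture
def small_config():
    """Small realistic design (noise, pool variation, mild distortions)."""
    return SimulationConfig(n_genes=80, rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20121102)
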