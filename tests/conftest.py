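import numpy as np
import pytest

from glycoscope import synthetic as syn


@pytest.fixture()
def quiet_raman_cfg():
    """Raman generator with every stochastic term switched off."""
    return syn.RamanGenConfig(
        baseline_slope_sd=0.0,
        baseline_offset_sd=0.0,
        gain_sd=0.0,
        amp_jitter_sd=0.0,
        effect_jitter_sd=0.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture()
def small_image_cfg():
    return syn.ImageGenConfig(
        size_px=256, n_collagen_fibers=50, n_elastin_fibers=25, noise_sd=0.0, seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
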