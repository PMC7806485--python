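"""Shared fixtures: small seeded simulations reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from shgmorph import estimate_tissue_mask, preset_config, sham_twin, simulate

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cleared_sim():
    """Healthy TDE-cleared stack: (stack, truth, config)."""
    cfg = preset_config("cleared", seed=11, volume_shape=(128, 128, 24))
    stack, truth = simulate(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def native_sim():
    """Uncleared stack with 200 µm attenuation: (stack, truth, config)."""
    cfg = preset_config("native", seed=7, volume_shape=(128, 128, 80))
    stack, truth = simulate(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def ctx_pair():
    """Matched CTX lesion / sham twin pair with tissue masks."""
    cfg = preset_config("ctx", seed=5, volume_shape=(128, 128, 60))
    ctx_stack, ctx_truth = simulate(cfg)
    sham_stack, sham_truth = simulate(sham_twin(cfg))
    return {
        "config": cfg,
        "ctx": (ctx_stack, ctx_truth),
        "sham": (sham_stack, sham_truth),
        "ctx_mask": estimate_tissue_mask(ctx_stack)[0],
        "sham_mask": estimate_tissue_mask(sham_stack)[0],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
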