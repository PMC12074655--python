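import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Four small synthetic scenes shared across tests."""
    from orthodetr.synthetic import SyntheticDatasetConfig, render_scene

    cfg = SyntheticDatasetConfig(n_images=4, image_side=64, semi_axis_min=5.0,
                                 semi_axis_max=10.0, seed=7)
    gen = np.random.default_rng(cfg.seed)
    return cfg, [render_scene(cfg, gen) for _ in range(cfg.n_images)]
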