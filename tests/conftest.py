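import numpy as np
import pytest

from photoacclim import synthetic_data as sd

#: irradiance grid used across the fitting tests
IRRADIANCES = np.array([33., 65., 98., 164., 264., 395., 580., 760.])


@pytest.fixture
def irradiances():
    return IRRADIANCES.copy()


@pytest.fixture
def noise_free_states():
    """Noise-free simulated steady states with ground truth."""
    cfg = sd.TurbidostatSimConfig(noise_cv=0.0, seed=0)
    return cfg, sd.simulate_steady_states(cfg)


@pytest.fixture
def small_expression():
    """Small planted-archetype expression bundle (fast)."""
    cfg = sd.ExpressionSimConfig(n_genes=(40, 40, 40, 40),
                                 gene_noise_sd=0.2, seed=11)
    return sd.simulate_expression(cfg)
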