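import numpy as np
import pytest

import babblereach as br

SCALED_SEEDS = (0, 1, 2)
SCALED_ITERATIONS = 200_000

TOY_SIZES = br.LayerSizes(motor=3, visual=2, hidden=4)


@pytest.fixture(scope="session")
def grids():
    """Default (motor, visual) tuning grids."""
    return br.motor_grid(), br.visual_grid()


@pytest.fixture()
def toy_params():
    """Small float64 model for gradient and oracle checks."""
    rng = np.random.default_rng(42)
    return br.ModelParams.initialize(TOY_SIZES, rng, scale=0.5, dtype=np.float64)


@pytest.fixture(scope="session")
def scaled_models():
    """Three independently seeded scaled babbling runs (200k iterations).

    Shared by the learning-signal, state-settling and reaching tests so the
    expensive training happens once per session.
    """
    out = []
    for seed in SCALED_SEEDS:
        cfg = br.TrainConfig(
            n_iterations=SCALED_ITERATIONS, seed=seed, checkpoint_every=10_000
        )
        params, log = br.train(cfg)
        out.append((cfg, params, log))
    return out
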