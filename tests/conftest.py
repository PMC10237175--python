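import numpy as np
import pytest

import cortexfold as cf


@pytest.fixture(scope="session")
def beta3_analysis():
    """Stability analysis at the brain-like stiffness ratio, shared."""
    return cf.analyze(3.0, n_k=40)


@pytest.fixture(scope="session")
def smoke_trajectory():
    """Quarter-resolution growth cascade (fast, qualitative).

    60 x (10 + 3) elements, coarse growth step; exercises folding,
    period doubling and contact detection within the unit-test budget.
    """
    cfg = cf.SimConfig(nx=60, ny_substrate=10, ny_layer=3, dtheta=4e-3,
                       theta_max=1.50, theta_watch=1.25, eig_every=1)
    return cf.run_growth(cfg)


@pytest.fixture(scope="session")
def smoke_metrics(smoke_trajectory):
    return cf.trajectory_metrics(smoke_trajectory)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
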