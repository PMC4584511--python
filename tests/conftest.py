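import numpy as np
import pytest

import normacc as na


@pytest.fixture(scope="session")
def triangles_observed():
    """Normative-observer choices on a 3-block triangles session."""
    hz = (0.1, 0.3, 0.7)
    trials = na.gen_triangles(
        na.TrianglesConfig(hazard_set=hz, n_trials_per_block=1000, sigma_over_d=0.33, seed=11)
    )
    obs = na.ObserverParams(
        model="normative",
        subjective_hazard={i: h for i, h in enumerate(hz)},
        gain=1 / 0.33**2,
        noise=1.0,
        seed=12,
    )
    return na.observe(trials, obs)


@pytest.fixture(scope="session")
def dots_observed():
    """Normative-observer choices on one low-hazard dots session."""
    data = na.gen_dots(na.DotsConfig(lam=0.1, n_trials=30, seed=21))
    obs = na.ObserverParams(model="normative", subjective_hazard=0.1, gain=0.13, seed=22)
    trials = na.observe(data, obs)
    return trials, data.frames


@pytest.fixture
def rng():
    return np.random.default_rng(0)
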