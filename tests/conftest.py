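import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ricesar as rs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calendar_2017():
    """The 14-acquisition 12-day calendar of the 2017-18 samba season."""
    return rs.generate_calendar(dt.date(2017, 8, 9), 14, 12, 0.0, 0)


@pytest.fixture(scope="session")
def small_scene():
    """48x48 noisy scene shared by read-only tests."""
    cfg = rs.SceneConfig(grid_shape=(48, 48))
    stack, truth = rs.build_scene(cfg, seed=7)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    """48x48 noiseless scene shared by read-only tests."""
    cfg = rs.SceneConfig(grid_shape=(48, 48)).noiseless()
    stack, truth = rs.build_scene(cfg, seed=7)
    return cfg, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def synthetic_training(calendar, n=12, seed=0, noise_sd=0.0, looks=None):
    """Training set of simulated rice dB curves on the given calendar."""
    import dataclasses

    from ricesar.signatures import TrainingSignatureSet

    gen = np.random.default_rng(seed)
    sigs, ids = [], []
    for k in range(n):
        sos = calendar.dates[int(gen.integers(3, 8))]
        m = rs.sample_rice_model(gen, sos)
        m = dataclasses.replace(m, noise_sd_db=noise_sd, speckle_looks=looks)
        sigs.append(rs.simulate_rice_signature(m, calendar, gen))
        ids.append(f"field-{k}")
    return TrainingSignatureSet(ids, np.stack(sigs), calendar)


@pytest.fixture(scope="session")
def make_training():
    return synthetic_training
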