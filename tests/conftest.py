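import numpy as np
import pytest

from reachkin import (
    SceneConfig,
    default_geometry,
    generate_session,
    preprocess_trajectory,
)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def clean_session():
    """One deterministic noise-free session shared by read-only tests."""
    cfg = SceneConfig(seed=7, noise_mm=0.0, noise_px=0.0)
    return generate_session(cfg, n_reaches=6)


@pytest.fixture(scope="session")
def clean_palm(clean_session):
    return preprocess_trajectory(clean_session.trajectories["palm"])


@pytest.fixture(scope="session")
def clean_pellet(clean_session):
    return preprocess_trajectory(clean_session.trajectories["pellet"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
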