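"""Shared fixtures: small phantoms keep the unit suite fast."""

import numpy as np
import pytest

from spinevb.phantom import PhantomConfig, generate_cohort, generate_spine_phantom


@pytest.fixture(scope="session")
def small_cfg() -> PhantomConfig:
    """A 3-body phantom on a reduced grid, cheap enough for unit tests."""
    return PhantomConfig(
        n_vbs=3,
        body_radii=(8.0, 7.0, 9.0),
        inter_body_offset=(0.0, 20.0, 0.0),
        offset_jitter_mm=(1.0, 1.5, 1.0),
        shape=(24, 80, 64),
        spacing=(2.0, 1.25, 1.25),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    return generate_spine_phantom(small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg, 4, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
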