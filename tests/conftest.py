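"""Shared fixtures: small synthetic images and one fully analyzed phantom."""

from __future__ import annotations

import numpy as np
import pytest

import lungmorph as lm
from lungmorph.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def disc_mask():
    """Centered disc of radius 20 in a 64x64 frame."""
    rr, cc = np.mgrid[0:64, 0:64]
    return (rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2


@pytest.fixture(scope="session")
def phantom_a():
    """One clean type-A phantom at acquisition scale."""
    return generate_phantom(
        PhantomSpec(rng_seed=17, image_size=(576, 768), n_generations=3, n_buds_target=4)
    )


@pytest.fixture(scope="session")
def analyzed_phantom(phantom_a):
    """Full pipeline result on the session phantom (computed once)."""
    return lm.analyze_image(phantom_a.rgb)
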