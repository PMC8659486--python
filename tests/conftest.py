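import logging

import numpy as np
import pytest

from renalseg.phantom import PhantomConfig, generate

logging.getLogger("renalseg").setLevel(logging.ERROR)

# Desk-scale phantom geometry used throughout the suite: 16 coronal slices of
# 64x64 keeps every stage exercised (central/peripheral slices, two kidneys,
# medullary lobes) while staying fast on one CPU.
SMALL_SHAPE = (16, 64, 64)
SMALL_T = 12


def make_phantom(seed=0, noise_sigma=0.0, **kwargs):
    cfg = PhantomConfig(
        shape=kwargs.pop("shape", SMALL_SHAPE),
        T=kwargs.pop("T", SMALL_T),
        noise_sigma=noise_sigma,
        seed=seed,
        **kwargs,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def clean_phantom():
    """One noise-free two-kidney phantom shared across tests."""
    return make_phantom(seed=0)


@pytest.fixture(scope="session")
def noisy_phantom():
    return make_phantom(seed=1, noise_sigma=4.0)


@pytest.fixture(scope="session")
def missing_kidney_phantom():
    return make_phantom(seed=2, abnormality="missing_kidney")
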