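"""Shared fixtures: small synthetic volumes and atlas libraries."""

from __future__ import annotations

import numpy as np
import pytest

import atlasfuse as af


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    """One default 32^3 phantom (target volume + truth label)."""
    return af.make_phantom(af.PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_subject():
    """A small subject with a 10-atlas library (default study conditions)."""
    vol, lab, atlases = af.make_dataset(1, master_seed=11)[0]
    return vol, lab, atlases


def random_label(rng, shape=(12, 12, 12), p=0.2, spacing=(1.0, 1.0, 1.0)):
    """A random non-empty binary mask on a small grid."""
    while True:
        data = (rng.random(shape) < p).astype(np.uint8)
        if data.any():
            break
    aff = np.diag([*spacing, 1.0])
    return af.LabelVolume(data, aff)
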