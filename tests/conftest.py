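"""Shared fixtures and dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from idseg.phantom import PhantomSpec, generate_phantom


def make_phantom_dataset(n, seed0=1, jitter=0.1, shape=(64, 64, 64)):
    """n phantoms with mildly jittered per-structure volumes (seeded)."""
    data = []
    for i in range(n):
        seed = seed0 + i
        rng = np.random.default_rng(seed)
        base = PhantomSpec(shape=shape, seed=seed)
        h = base.hippo_reference_volume() * (min(shape) / 64.0) ** 3
        a = base.amygdala_reference_volume() * (min(shape) / 64.0) ** 3
        sv = {
            "left_hippocampus": h * float(rng.uniform(1 - jitter, 1 + jitter)),
            "right_hippocampus": h * float(rng.uniform(1 - jitter, 1 + jitter)),
            "left_amygdala": a * float(rng.uniform(1 - jitter, 1 + jitter)),
            "right_amygdala": a * float(rng.uniform(1 - jitter, 1 + jitter)),
        }
        data.append(generate_phantom(PhantomSpec(shape=shape, seed=seed,
                                                 structure_volumes=sv)))
    return data


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def tiny_phantoms():
    """Small 32-grid phantoms for fast training smoke tests."""
    return make_phantom_dataset(6, seed0=50, shape=(32, 32, 32))
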