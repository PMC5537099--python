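from dataclasses import replace

import pytest

from musclemap.phantom import PhantomSpec

#: Small, fast phantom spec for unit tests (64 px, thinner ring).
SMALL_SPEC = PhantomSpec(image_size=64, muscle_ring_thickness=4.0)

#: Deterministic tissue HU: no noise, no blur, no pockets, no edema.
CLEAN_SPEC = replace(
    SMALL_SPEC,
    noise_sd=0.0,
    smoothing_sigma=0.0,
    intramuscular_fat_fraction=0.0,
    edema_probability=0.0,
)

#: Minimal spec for end-to-end plumbing tests (fastest legal size).
TINY_SPEC = PhantomSpec(image_size=32, muscle_ring_thickness=2.0, n_organs=2)


@pytest.fixture
def small_spec() -> PhantomSpec:
    return SMALL_SPEC


@pytest.fixture
def clean_spec() -> PhantomSpec:
    return CLEAN_SPEC


@pytest.fixture
def tiny_spec() -> PhantomSpec:
    return TINY_SPEC
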