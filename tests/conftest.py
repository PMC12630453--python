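"""Shared fixtures: small phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from leafarch.phantom import (
    GasExTruth,
    PhantomSpec,
    make_channel_phantom,
    make_inclusion_phantom,
    make_leaf_phantom,
    reference_protocol,
    records_to_frame,
    simulate_gas_exchange,
)


@pytest.fixture(scope="session")
def leaf_phantom():
    """Default layered leaf phantom with its instances and truth."""
    return make_leaf_phantom(PhantomSpec(rng_seed=7))


@pytest.fixture(scope="session")
def small_leaf_phantom():
    """Smaller, faster leaf phantom for metric unit tests."""
    spec = PhantomSpec(
        dims=(64, 72, 72),
        outside_top=4,
        adaxial_pavement=4,
        palisade_depth=22,
        spongy_depth=24,
        abaxial_pavement=4,
        palisade_radius=5.0,
        palisade_spacing=10,
        spongy_cell_radius=7.5,
        rng_seed=3,
    )
    return make_leaf_phantom(spec)


@pytest.fixture(scope="session")
def straight_channel():
    return make_channel_phantom("straight", dims=(64, 96, 64))


@pytest.fixture(scope="session")
def serpentine_channel():
    # full-size geometry: the channel must be narrow relative to its path
    # for the polyline idealisation to hold at the corners
    return make_channel_phantom("serpentine")


@pytest.fixture(scope="session")
def blocked_channel():
    return make_channel_phantom("blocked", dims=(64, 96, 64))


@pytest.fixture(scope="session")
def air_inclusions():
    radii = [4.0, 6.0, 8.0, 10.0]
    centers = [(16, 14, 14), (18, 14, 44), (18, 44, 16), (20, 46, 46)]
    return make_inclusion_phantom(list(zip(centers, radii)), phase="air", dims=(64, 64, 64))


@pytest.fixture(scope="session")
def tissue_inclusions():
    radii = [4.0, 6.0, 8.0, 10.0]
    centers = [(16, 14, 14), (18, 14, 44), (18, 44, 16), (20, 46, 46)]
    return make_inclusion_phantom(list(zip(centers, radii)), phase="tissue", dims=(64, 64, 64))


@pytest.fixture(scope="session")
def gasex_truth():
    return GasExTruth(rng_seed=11)


@pytest.fixture(scope="session")
def gasex_records_clean(gasex_truth):
    """Zero-noise records over the reference protocol (exact-Yin limit)."""
    return records_to_frame(
        simulate_gas_exchange(gasex_truth, reference_protocol(yin_o2=0.0))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
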