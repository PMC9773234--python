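import numpy as np
import pytest

from granulocell import GranularBed, generate_particles, make_fixture, settle_bed


@pytest.fixture(scope="session")
def mini_bed_settled():
    """A settled 16-particle single-layer bed (shared, read-only)."""
    scene = make_fixture("mini_bed_4x4", seed=3)
    return settle_bed(scene.bed, max_steps=800_000)


@pytest.fixture(scope="session")
def small_bed_settled():
    """A settled 3-layer bed in a (10d)^3 box (shared, read-only)."""
    bed = generate_particles(3, box=(10.0, 10.0, 10.0), seed=11)
    return settle_bed(bed, max_steps=2_000_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
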