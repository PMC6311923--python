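import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from dhsnet import (
    FixtureSpec,
    generate_fixture,
    sample_negatives,
)


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale corpus spec: enough samples for distributional checks,
    small enough to build in seconds."""
    return FixtureSpec(
        n_chromosomes=2,
        chrom_length=150_000,
        n_positives=200,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    genomes, positives, excluded = generate_fixture(small_spec)
    gmap = {g.chrom_name: g for g in genomes}
    return gmap, positives, excluded


@pytest.fixture(scope="session")
def small_corpus(small_fixture):
    gmap, positives, excluded = small_fixture
    negatives = sample_negatives(gmap, positives, excluded, seed=5)
    return gmap, positives, negatives, excluded


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
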