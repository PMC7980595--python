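import numpy as np
import pytest
from hypothesis import settings

import enhseq as e

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small two-type simulation shared by read-only tests."""
    return e.simulate(e.SimConfig(
        genome_length=400_000, n_chromosomes=2, enhancers_per_type=60, seed=11))


@pytest.fixture(scope="session")
def small_data(small_sim):
    """Prepared positives/backgrounds/dictionaries for typeA of small_sim."""
    return e.prepare_from_sim(small_sim, "typeA", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_segment(rng, L=30, F=5):
    """A random ACGT segment with flanks, for featurizer/oracle tests."""
    letters = np.array(list("ACGT"))
    s = "".join(rng.choice(letters, size=L + 2 * F))
    return e.EnhancerSegment(
        core=s[F:F + L], left_flank=s[:F], right_flank=s[F + L:],
        origin=e.GenomicInterval("chrT", 100, 100 + L),
    )
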