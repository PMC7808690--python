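import numpy as np
import pytest

from clonemut import synthetic_data as sd
from clonemut.catalog_io import Reference


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_reference():
    """Tiny fixed reference for hand-checkable examples."""
    return Reference({
        "chr1": "ACGTACGTTTTTTGCAGGACTTCGATCGGGCATTACCGGA",
        "chr2": "TTCGATTCCGGAACCGGTTAACGTACGT",
    })


@pytest.fixture(scope="session")
def small_cfg():
    return sd.SimConfig(seed=11, genome_length=200_000, n_chromosomes=2,
                        n_samples=12, n_donors=8, background_median=300.0,
                        background_sigma=0.4)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    seqs = sd.make_reference(small_cfg)
    cohort = sd.simulate_cohort(small_cfg, seqs)
    return seqs, cohort


@pytest.fixture(scope="session")
def small_reference(small_cohort):
    seqs, _ = small_cohort
    return Reference(seqs)


def random_sequence(rng, n, p_gc=0.5):
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))
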