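import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def canonical_family():
    """The canonical seven-lesion family (synthetic stand-in, seed 1).

    300-nt flanks keep the session fast; the lesion coordinates themselves
    do not depend on flank size.
    """
    from aadscan.synthetic_data import generate_canonical_family

    return generate_canonical_family(seed=1, flank_nt=300)


@pytest.fixture(scope="session")
def classified_canonical_family(canonical_family):
    """Classification reports for every locus of the canonical family."""
    from aadscan.pseudogene import classify_locus

    reference, loci, sites, truth = canonical_family
    reports = {
        locus.label: classify_locus(locus, reference, sites) for locus in loci
    }
    return reference, loci, sites, truth, reports


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_dna(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))
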