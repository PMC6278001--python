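import pytest

from lethalmap.models import VariantCall
from lethalmap.simulate import CohortConfig, GeneratorConfig, simulate_cohort, simulate_genome


@pytest.fixture(scope="session")
def genome():
    """Default synthetic chromosome, shared across tests (read-only)."""
    return simulate_genome(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def cohort(genome):
    """Default 130-strain cohort (23 marker failures, 4 low-coverage)."""
    return simulate_cohort(genome, CohortConfig(seed=2))


def make_variant(
    alt_fwd=5, alt_rev=5, ref_fwd=3, ref_rev=2, pos=100, chrom="chrI", ref="A", alt="T"
):
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        alt_fwd=alt_fwd, alt_rev=alt_rev, ref_fwd=ref_fwd, ref_rev=ref_rev,
    )
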