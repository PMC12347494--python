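import numpy as np
import pytest

from rtmut import GenomeSequence
from rtmut.profiling import TrinucFrequencies
from rtmut.synthetic import (
    SyntheticCohortSpec,
    SyntheticEffect,
    SyntheticGenomeSpec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def toy_genome():
    """Tiny hand-written genome for classification tests."""
    return GenomeSequence(
        {
            "1": "ACATGCGTACGTTTTTGGGACA",
            "2": "NCATTTACGANN",
        }
    )


@pytest.fixture(scope="session")
def uniform_trinuc():
    return TrinucFrequencies(np.ones(32))


@pytest.fixture(scope="session")
def small_cohort():
    """Small but complete cohort reused by pipeline-level tests."""
    spec = SyntheticCohortSpec(
        genome=SyntheticGenomeSpec(n_chromosomes=2, chrom_length=200_000),
        n_controls=4,
        n_replicates=2,
        baseline_burden=800.0,
        indel_burden=40.0,
        seed=7,
        effects=[
            ("null_a", SyntheticEffect()),
            ("lrr_shift", SyntheticEffect(
                spectrum_shift={"A[C>T]A": 0.25}, rt_restriction="late")),
        ],
    )
    return generate_cohort(spec)
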