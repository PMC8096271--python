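import numpy as np
import pandas as pd
import pytest

from vntrkit.reference import ReferenceTRLocus, ReferenceTRSet
from vntrkit.simulate import SimulationConfig, TrueGenotypeTable, generate_reference, sample_cohort

_NA = -128


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_populations=1,
        samples_per_population=4,
        n_loci=30,
        pattern_length_range=(7, 12),
        ref_copies_range=(2.0, 4.5),
        allele_cgl_range=(-2, 1),
        indistinguishable_fraction=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_cohort_truth(small_config, small_reference):
    ref_set, _ = small_reference
    return sample_cohort(ref_set, small_config)


@pytest.fixture
def toy_locus():
    def make(locus_id=1, pattern="ACGTACG", ref_copies=4.0, chrom="chr1", start=100):
        end = start + round(len(pattern) * ref_copies)
        return ReferenceTRLocus(
            locus_id=locus_id,
            chrom=chrom,
            start=start,
            end=end,
            pattern=pattern,
            ref_copies=ref_copies,
        )

    return make


def make_truth_table(allele_pairs, chrom="chr1", sample_id="S0", sex="F", population="POP1"):
    """A one-sample truth table from a list of per-locus allele pairs."""
    n = len(allele_pairs)
    A = np.full((n, 1, 2), _NA, dtype=np.int16)
    for i, pair in enumerate(allele_pairs):
        for k, a in enumerate(pair):
            A[i, 0, k] = a
    return TrueGenotypeTable(
        samples=pd.DataFrame(
            [{"sample_id": sample_id, "sex": sex, "population": population}]
        ),
        locus_ids=list(range(1, n + 1)),
        chrom_of={i + 1: chrom for i in range(n)},
        alleles=A,
    )
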