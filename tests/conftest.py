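import numpy as np
import pytest

from dapcy.popsim import SimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """4 populations x 50 samples x 1000 SNPs at moderate differentiation."""
    return simulate_cohort(SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """3 populations x 20 samples x 200 SNPs; fast fixture for I/O tests."""
    return simulate_cohort(
        SimulationSpec(
            n_populations=3,
            samples_per_population=20,
            n_snps=200,
            fst=0.15,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def missing_cohort():
    """Cohort with 5% missing calls."""
    return simulate_cohort(
        SimulationSpec(
            n_populations=3,
            samples_per_population=15,
            n_snps=150,
            fst=0.12,
            missing_rate=0.05,
            seed=13,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def write_minimal_vcf(path, body_rows, samples=("S1", "S2", "S3")):
    """Hand-written VCF for encoding tests; body_rows are full data lines."""
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in body_rows:
            fh.write(row + "\n")
    return path
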