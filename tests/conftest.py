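import numpy as np
import pytest

from lowmeth.genome import generate_genome, generate_methylome
from lowmeth.simulate import SampleSpec, simulate_sample


@pytest.fixture(scope="session")
def toy_genome():
    """60-kb single-contig genome with repeats and a 600-bp rDNA-like unit."""
    return generate_genome(
        {"chr1": 60_000},
        seed=101,
        repeat_density=0.2,
        repeat_length=1000,
        rdna_contig="chr1",
        rdna_start=40_001,
        rdna_unit_length=600,
        min_read_length=100,
    )


@pytest.fixture(scope="session")
def plain_genome():
    """Repeat-free two-contig genome: every locus uniquely placeable."""
    return generate_genome(
        {"chrA": 50_000, "chrB": 30_000},
        seed=7,
        repeat_density=0.0,
        rdna_contig="chrB",
        rdna_start=20_001,
        rdna_unit_length=500,
        min_read_length=100,
    )


@pytest.fixture(scope="session")
def toy_methylome(toy_genome):
    return generate_methylome(
        toy_genome, seed=202, background_mean=0.68, repeat_mean=0.87, rdna_mean=0.75
    )


@pytest.fixture(scope="session")
def plain_methylome(plain_genome):
    return generate_methylome(
        plain_genome, seed=303, background_mean=0.75, repeat_mean=0.87, rdna_mean=0.75
    )


@pytest.fixture(scope="session")
def clean_simulation(plain_genome, plain_methylome):
    """Error-free reads from the repeat-free genome, with ground truth."""
    spec = SampleSpec(
        sample_id="clean", n_reads=1500, read_length=100,
        conversion_efficiency=0.98, error_rate=0.0, seed=404,
    )
    return simulate_sample(plain_genome, plain_methylome, spec, mode="reads")
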