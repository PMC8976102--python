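"""Shared fixtures: expensive simulations are session-scoped so several
tests can interrogate the same synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from genomesurvey import _seq
from genomesurvey.kmer import count_kmers
from genomesurvey.simulate import (SimulationParams, simulate_diploid_genome,
                                   simulate_reads)


def random_dna(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return _seq.decode(rng.integers(0, 4, n).astype(np.uint8))


@pytest.fixture(scope="session")
def het_sim():
    """500-kb diploid at heterozygosity 0.39%, no repeats, ~60x k-mer depth,
    error-free reads — the heterozygosity-recovery study condition."""
    params = SimulationParams(
        genome_length=500_000, heterozygosity=0.0039, repeat_fraction=0.0,
        ssr_density=0.0, sex_system="ZZ_male", coverage=60 * 150 / 134,
        error_rate=0.0, seed=11)
    genome = simulate_diploid_genome(params)
    reads = simulate_reads(genome, params)
    spectrum = count_kmers(reads, 17)
    return params, genome, reads, spectrum


@pytest.fixture(scope="session")
def repeat_sim():
    """500-kb diploid with 32.6% planted repeats at heterozygosity 0.39%."""
    params = SimulationParams(
        genome_length=500_000, heterozygosity=0.0039, repeat_fraction=0.326,
        ssr_density=0.0, sex_system="ZZ_male", coverage=60 * 150 / 134,
        error_rate=0.0, seed=5)
    genome = simulate_diploid_genome(params)
    reads = simulate_reads(genome, params)
    spectrum = count_kmers(reads, 17)
    return params, genome, reads, spectrum


@pytest.fixture(scope="session")
def zw_sim():
    """300-kb ZW female with 10 planted W segments plus the conspecific ZZ
    male; female reads at 40x — the sex-marker study condition."""
    from genomesurvey.simulate import simulate_survey_pair

    params = SimulationParams(
        genome_length=300_000, heterozygosity=0.0039, repeat_fraction=0.2,
        coverage=40.0, w_segment_count=10,
        w_segment_lengths=(1000, 1500, 2000), seed=42)
    male, female = simulate_survey_pair(params)
    reads = simulate_reads(female, params)
    return params, male, female, reads
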