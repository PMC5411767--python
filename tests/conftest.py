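"""Shared fixtures: small simulated genomes and read sets.

Everything is generated programmatically and seeded, so the suite needs
no data files and is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from miniolc import simdata
from miniolc.config import PipelineConfig
from miniolc.sketch import TfIdfParams, count_kmers


@pytest.fixture(scope="session")
def small_genome():
    """20 kb random genome, no repeats."""
    return simdata.simulate_genome(simdata.GenomeSpec(length=20_000, seed=11))


@pytest.fixture(scope="session")
def small_reads(small_genome):
    """~15x noisy reads (10% error) over the small genome, with truth."""
    spec = simdata.ReadSimSpec(coverage=15, error_rate=0.10, seed=7,
                               length_min=800, length_max=4000, length_mu=7.6)
    return simdata.simulate_reads(small_genome.sequence, spec)


@pytest.fixture(scope="session")
def clean_reads(small_genome):
    """Error-free reads over the small genome."""
    spec = simdata.ReadSimSpec(coverage=12, error_rate=0.0, seed=13,
                               length_min=800, length_max=4000, length_mu=7.6)
    return simdata.simulate_reads(small_genome.sequence, spec)


@pytest.fixture(scope="session")
def spectrum(small_reads):
    reads, _ = small_reads
    return count_kmers(reads, 16, 0.02)


@pytest.fixture(scope="session")
def tfidf_params():
    return TfIdfParams()


@pytest.fixture()
def cfg():
    return PipelineConfig(genome_size=20_000, seed=1)


def noisy_copy(seq: str, rate: float, seed: int, subs_only: bool = False) -> str:
    """A mutated copy of `seq` at the given per-base error rate (forward
    strand), used to build overlap pairs of known divergence."""
    rng = np.random.default_rng(seed)
    mix = (1.0, 0.0, 0.0) if subs_only else (1 / 3, 1 / 3, 1 / 3)
    spec = simdata.ReadSimSpec(coverage=0.9, error_rate=rate, seed=seed,
                               length_min=len(seq), length_max=len(seq),
                               error_mix=mix)
    reads, truth = simdata.simulate_reads(seq, spec)
    from miniolc.hashing import revcomp

    s = reads[0][1]
    return revcomp(s) if truth[0].strand == "-" else s
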