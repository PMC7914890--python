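"""Shared fixtures: small deterministic genomes and read builders."""
from __future__ import annotations

import numpy as np
import pytest

from stablefrag.records import FastqRead
from stablefrag.seqs import Genome
from stablefrag.simdata import make_genome


@pytest.fixture(scope="session")
def genome2k():
    """2 kb random genome, fixed seed, no duplications."""
    genome, _truth = make_genome(2000, 0.5, seed=20)
    return genome


@pytest.fixture(scope="session")
def genome_dup():
    """5 kb genome with two 60-bp duplicated loci."""
    genome, truth = make_genome(5000, 0.5, n_duplicated_loci=2, seed=21)
    return genome, truth


def make_read(bases: str, rid: str = "r", q: int = 40, mate: int = 0) -> FastqRead:
    return FastqRead(rid, bases, [q] * len(bases), mate)


@pytest.fixture
def read_factory():
    return make_read
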