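import numpy as np
import pytest

from sirscan.engine import IRParams
from sirscan.seqio import GenomeRecord

from oracles import random_dna


@pytest.fixture
def default_params() -> IRParams:
    return IRParams()


@pytest.fixture
def make_genome():
    """Factory for seeded random genomes at a given GC fraction."""
    def _make(seed: int, length: int, gc: float = 0.37,
              genome_id: str | None = None) -> GenomeRecord:
        rng = np.random.default_rng(seed)
        return GenomeRecord(id=genome_id or f"g{seed}",
                            seq=random_dna(rng, length, gc))
    return _make
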