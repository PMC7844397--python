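import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from isogrow import syndata


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_small():
    """A 40-gene transcriptome with AS pairs, SSRs and noncoding truth."""
    cfg = syndata.SimConfig(n_genes=40, as_pair_fraction=0.5, seed=5)
    transcripts, truth = syndata.simulate_transcriptome(cfg)
    return cfg, transcripts, truth


@pytest.fixture(scope="session")
def clean_read_sim():
    """Error-free reads with nFL and chimeric truth labels."""
    cfg = syndata.SimConfig(
        n_genes=25,
        seed=3,
        read_error_rate=0.0,
        chimera_rate=0.1,
        nfl_dropout_rate=0.2,
        ccs_fail_rate=0.0,
    )
    transcripts, truth = syndata.simulate_transcriptome(cfg)
    reads = syndata.simulate_long_reads(transcripts, cfg)
    return cfg, transcripts, reads
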