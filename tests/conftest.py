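import numpy as np
import pytest

from structome import SimConfig, TranscriptModel, simulate_structurome, simulate_rtstops


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic structurome with a planted KO structuring effect."""
    cfg = SimConfig(n_transcripts=20, n_binding_sites=30, n_m6a=40, n_ythdf1=40,
                    delta=0.4, depth=20.0, seed=7)
    transcriptome, truth, sites = simulate_structurome(cfg)
    tables = simulate_rtstops(transcriptome, truth, cfg)
    return cfg, transcriptome, truth, sites, tables


@pytest.fixture
def toy_transcript():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    return TranscriptModel("toy", "toygene", seq, 50, 200)
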