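import numpy as np
import pytest

from phosfx import MockBackend, ProteinRecord, SynthConfig, simulate
from phosfx.pipeline import embed_all


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_proteins():
    return [
        ProteinRecord(id="P1", sequence="MASTYKLRRSDE"),
        ProteinRecord(id="P2", sequence="GGSGGTGGYGGSGG"),
        ProteinRecord(id="P3", sequence="S"),
    ]


@pytest.fixture
def fasta_path(tmp_path, toy_proteins):
    from phosfx import write_fasta

    path = tmp_path / "toy.fasta"
    write_fasta(toy_proteins, path)
    return path


@pytest.fixture(scope="session")
def small_synth():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SynthConfig(n_proteins=40, n_sites=60, n_pairs=40, seed=5)
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def small_synth_embeddings(small_synth):
    _, data = small_synth
    return embed_all(data.proteins, MockBackend(dim=16, seed=0))
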