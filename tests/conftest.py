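import pytest

from radpep.simulate import SimConfig, gen_transcriptome


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def transcriptome(sim_config):
    """(contigs, transcripts, proteome) shared across tests."""
    return gen_transcriptome(sim_config)
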