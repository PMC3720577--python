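import pytest

from mycoseq import simulate_transcriptomes


@pytest.fixture(scope="session")
def small_transcriptome():
    """A compact two-tissue simulation shared across expression tests."""
    return simulate_transcriptomes(
        n_genes=60,
        shared_fraction=0.8,
        mutation_rate=0.02,
        homolog_families=(3,),
        seed=101,
    )


@pytest.fixture(scope="session")
def small_transcriptome_files(small_transcriptome, tmp_path_factory):
    d = tmp_path_factory.mktemp("transcriptome")
    return small_transcriptome.write(d)
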