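import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import genefamkit as gk


@pytest.fixture(scope="session")
def gene_table():
    return gk.load_gene_table()


@pytest.fixture(scope="session")
def gene_models(gene_table):
    return {m.gene_id: m for m in gk.gene_models_from_table(gene_table)}


@pytest.fixture(scope="session")
def genome_sim():
    """One small simulated genome pair with planted blocks and tandems."""
    return gk.simulate_genome_pair(gk.GenomeSimSpec(rng_seed=11))


@pytest.fixture()
def toy_gff3(tmp_path):
    def write(text: str, name: str = "toy.gff3") -> Path:
        p = tmp_path / name
        p.write_text(text)
        return p

    return write
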