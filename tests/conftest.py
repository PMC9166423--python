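import pytest

from cprlib import PipelineConfig
from cprlib import synthetic_data as sd


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_bin():
    """A 10-contig bin with 3 planted foreign and 2 planted viral contigs."""
    return sd.make_bin(seed=42, n_contigs=10, genes_per_contig=10,
                       foreign_frac=0.3, viral_frac=0.2)


def gene_taxonomy(bin_):
    """Planted per-gene taxonomy straight from the generator's labels."""
    return {g.id: g.best_hit_class for g in bin_.genes.values()}
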