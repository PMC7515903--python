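import numpy as np
import pytest

from silkforge._seq import translate
from silkforge.genes import SpidroinGeneModel, generate_gene, make_contig_fixtures
from silkforge.reads import ReadSimConfig, simulate_long_reads, simulate_short_reads


@pytest.fixture(scope="session")
def small_gene():
    """A compact MiSp-like gene: 300 nt unit x 8 identical copies."""
    model = SpidroinGeneModel.from_family(
        "MiSp", species_seed=7, unit_len=300, n_copies=8,
        per_copy_divergence=0.0, species_divergence=0.0,
    )
    return generate_gene(model, seed=11)


@pytest.fixture(scope="session")
def clean_read_bundle(small_gene):
    """Error-free 30x short reads + error-free spanning long reads."""
    cfg = ReadSimConfig(rng_seed=5, short_error_rate=0.0,
                        long_error_rate=0.0, span_fraction=1.0)
    r1, r2 = simulate_short_reads([(small_gene.gene_id, small_gene.cds)], cfg)
    lr = simulate_long_reads([(small_gene.gene_id, small_gene.cds)], cfg)
    short = {r.name: r.seq for r in r1 + r2}
    long_reads = {r.name: r.seq for r in lr}
    return short, long_reads


@pytest.fixture(scope="session")
def gene_profiles(small_gene):
    g = small_gene
    return [
        ("q_NTD", "NTD", translate(g.ntd)),
        ("q_CTD", "CTD", translate(g.ctd)),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
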