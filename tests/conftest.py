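import numpy as np
import pandas as pd
import pytest

from cellherit.config import SimConfig
from cellherit.simulate import generate_atlas, generate_gene_annotation


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=1, n_genes=300, n_clusters=6, n_superclusters=3,
                     n_dissections=4, n_snps=1000, n_individuals=500, n_panel=200)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return generate_gene_annotation(small_config)


@pytest.fixture(scope="session")
def small_atlas(small_config, small_annotation):
    return generate_atlas(small_config, small_annotation)


@pytest.fixture()
def clean_annotation():
    """Handmade annotation: all protein-coding, autosomal, non-eMHC."""
    def make(genes, chrom="chr1", spacing=200_000, length=10_000):
        n = len(genes)
        starts = np.arange(n) * spacing + 1_000
        return pd.DataFrame({
            "gene": genes,
            "chrom": chrom,
            "start": starts,
            "end": starts + length,
            "tss": starts,
            "strand": "+",
            "biotype": "protein_coding",
            "emhc": False,
        })
    return make
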