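import pytest

from spotarray import datasets, layout, probes
from spotarray.catalog import TrnaGene, _build_catalog


def make_gene(aa, anticodon, body, gene_id, locus=None):
    """Toy gene: CCA-less body plus the universal terminal CCA."""
    return TrnaGene(
        gene_id=gene_id,
        amino_acid=aa,
        anticodon=anticodon,
        sequence=body + "CCA",
        has_cca=True,
        locus=locus,
    )


def build_toy_catalog(entries):
    """Catalog from (aa, anticodon, body[, locus]) tuples; one gene each."""
    genes = [
        make_gene(e[0], e[1], e[2], f"toy{i}", e[3] if len(e) > 3 else None)
        for i, e in enumerate(entries)
    ]
    return _build_catalog(genes)


@pytest.fixture(scope="session")
def ecoli_like_catalog():
    """Synthetic catalog with the E. coli tRNA complement's structure:
    86 genes, 48 species, 40 isoacceptor families."""
    return datasets.synthetic_catalog()


@pytest.fixture(scope="session")
def panel(ecoli_like_catalog):
    return probes.design(ecoli_like_catalog)


@pytest.fixture(scope="session")
def array(panel):
    return layout.build_layout(panel, replicates=8)
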