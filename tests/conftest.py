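import random

import pytest

from allelescope import (annotate, call_variants, global_align, make_allele_pair,
                         merge_complex, protein_effect)
from allelescope.genemodel import AlleleSequence, GeneModel


@pytest.fixture(scope="session")
def pair():
    """The packaged synthetic W3/w3 allele pair (seed 1)."""
    return make_allele_pair(seed=1)


@pytest.fixture(scope="session")
def merged_catalog(pair):
    """Merged, annotated catalog with protein effects for the packaged pair."""
    aln = global_align(pair.reference, pair.derived)
    catalog = merge_complex(call_variants(aln, ref_allele=pair.reference), window=10)
    annotate(catalog, pair.model)
    protein_effect(catalog, pair.reference, pair.derived, pair.model)
    return catalog


@pytest.fixture
def toy_model():
    """Two-exon toy gene: exon1 1-100, intron1 101-200, exon2 201-300."""
    return GeneModel(gene_id="toy", upstream_length=50,
                     exons=((1, 100), (201, 300)))


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20151214)
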