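import numpy as np
import pytest

from trnadup.io import AnnotationSet
from trnadup.model import TRNAGene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene(
    gene_id,
    start,
    end=None,
    seq="",
    species="Tst",
    seq_id="sc1",
    strand="+",
    isotype="Gly",
    anticodon="GCC",
    introns=(),
    note="",
):
    """Convenience constructor for a TRNAGene with consistent coordinates."""
    if end is None:
        end = start + len(seq) - 1 if seq else start + 71
    return TRNAGene(
        gene_id=gene_id,
        species=species,
        seq_id=seq_id,
        start=start,
        end=end,
        strand=strand,
        isotype=isotype,
        anticodon=anticodon,
        genomic_seq=seq,
        intron_spans=tuple(introns),
        note=note,
    )


def make_annotation(genes):
    return AnnotationSet(genes=list(genes))


@pytest.fixture
def gene_factory():
    return make_gene
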