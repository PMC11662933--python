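import numpy as np
import pytest

from snordpipe.genome import GeneModel, TranscriptModel, filter_transcripts
from snordpipe.snorna import build_snorna_registry
from snordpipe.synthetic import build_toy_annotation


@pytest.fixture(scope="session")
def registry():
    return build_snorna_registry(seed=11)


@pytest.fixture(scope="session")
def annotation():
    """60-gene toy annotation with sequences (session-scoped; treat as read-only)."""
    return build_toy_annotation(60, n_chroms=2, gc_targets=0.45, seed=101)


@pytest.fixture(scope="session")
def retained(annotation):
    genes, _ = annotation
    kept, _ = filter_transcripts(genes)
    return kept


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_transcript(
    tx_id="T1",
    gene_id="G1",
    chrom="chr1",
    strand="+",
    exons=((100, 200), (300, 400)),
    cds=(),
    tsl=1,
    basic=True,
):
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds=tuple(cds),
        support_level=tsl,
        basic=basic,
    )


def make_gene(gene_id="G1", transcripts=None, **tx_kwargs):
    if transcripts is None:
        transcripts = (make_transcript(gene_id=gene_id, **tx_kwargs),)
    return GeneModel(gene_id=gene_id, transcripts=tuple(transcripts))
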