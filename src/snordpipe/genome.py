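"""Gene and transcript models with strand-aware UTR/CDS partitioning.

A :class:`TranscriptModel` stores its exon and CDS footprint; the 5'/3' UTRs
are derived as exonic space minus CDS space, split by which side of the CDS
they fall on (on the ``-`` strand the 5' UTR occupies the highest genomic
coordinates). Transcripts carry the two GENCODE annotation attributes the
downstream filters need: the transcript support level (TSL, 1-5 or missing)
and the ``basic`` tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval, Span, merge, subtract


class AnnotationError(ValueError):
    """Structural problem in an annotation (orphan features, bad nesting)."""


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Span, ...]
    cds: tuple[Span, ...] = ()
    support_level: Optional[int] = None
    basic: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        exons = tuple(merge(self.exons))
        object.__setattr__(self, "exons", exons)
        cds = tuple(merge(self.cds))
        object.__setattr__(self, "cds", cds)
        if not exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        if cds and subtract(cds, exons):
            raise AnnotationError(
                f"transcript {self.transcript_id}: CDS outside exon space"
            )

    @property
    def span(self) -> Span:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_span(self) -> Optional[Span]:
        return (self.cds[0][0], self.cds[-1][1]) if self.cds else None

    @property
    def utr5(self) -> tuple[Span, ...]:
        return self._utrs()[0]

    @property
    def utr3(self) -> tuple[Span, ...]:
        return self._utrs()[1]

    def _utrs(self) -> tuple[tuple[Span, ...], tuple[Span, ...]]:
        if not self.cds:
            return (), ()
        noncds = subtract(self.exons, self.cds)
        cs, ce = self.cds_span  # type: ignore[misc]
        left = tuple(s for s in noncds if s[1] <= cs)
        right = tuple(s for s in noncds if s[0] >= ce)
        if self.strand == "+":
            return left, right
        return right, left

    @property
    def introns(self) -> tuple[Span, ...]:
        return tuple(subtract([self.span], self.exons))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    symbol: str = ""
    biotype: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene {self.gene_id}: transcripts span multiple chroms/strands"
            )
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"transcript {t.transcript_id} assigned to wrong gene"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        s = min(t.span[0] for t in self.transcripts)
        e = max(t.span[1] for t in self.transcripts)
        return GenomicInterval(self.chrom, s, e, self.strand)

    @property
    def exon_union(self) -> list[Span]:
        return merge(sp for t in self.transcripts for sp in t.exons)


def filter_transcripts(
    genes: Iterable[GeneModel],
    tsl_max: int = 3,
    require_basic: bool = True,
) -> tuple[dict[str, list[TranscriptModel]], list[str]]:
    """Keep transcripts with TSL 1..``tsl_max`` and (optionally) the basic tag.

    A missing or non-numeric TSL fails the filter. Returns the mapping
    ``gene_id -> retained transcripts`` (genes with none retained are omitted)
    and the list of gene_ids that lost all transcripts.
    """
    kept: dict[str, list[TranscriptModel]] = {}
    empty: list[str] = []
    for gene in genes:
        retained = [
            t
            for t in gene.transcripts
            if t.support_level is not None
            and 1 <= t.support_level <= tsl_max
            and (t.basic or not require_basic)
        ]
        if retained:
            kept[gene.gene_id] = retained
        else:
            empty.append(gene.gene_id)
    return kept, empty


def exonic_gc(
    gene: GeneModel,
    sequence: str,
    transcripts: Optional[Sequence[TranscriptModel]] = None,
) -> tuple[int, float]:
    """(length, GC fraction) of the union of exons over ``transcripts``.

    ``sequence`` is the gene-span sequence (index 0 = ``gene.span.start``).
    GC content is strand-symmetric, so the + strand sequence suffices.
    """
    txs = gene.transcripts if transcripts is None else transcripts
    exons = merge(sp for t in txs for sp in t.exons)
    off = gene.span.start
    length = 0
    gc = 0
    for s, e in exons:
        seg = sequence[s - off : e - off]
        length += len(seg)
        gc += sum(seg.count(b) for b in "GCgc")
    return length, (gc / length if length else 0.0)
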