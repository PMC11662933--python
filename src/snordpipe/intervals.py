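"""Genomic intervals and the small interval set-algebra the pipeline is built on.

All coordinates in this package are 0-based, half-open ``[start, end)``.
GTF input/output is converted at the boundary (see :mod:`snordpipe.io`).

The algebra operates on plain ``(start, end)`` integer pairs; strand and
chromosome bookkeeping stays with the caller. Interval lists returned by
:func:`merge`, :func:`subtract` and :func:`intersect` are sorted and disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")

Span = tuple[int, int]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open bounds; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge(spans: Iterable[Span]) -> list[Span]:
    """Union of spans as a sorted list of disjoint spans (touching spans fuse)."""
    out: list[Span] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(a: Sequence[Span], b: Sequence[Span]) -> list[Span]:
    """Base pairs in ``a`` but not in ``b``; inputs need not be disjoint."""
    a = merge(a)
    b = merge(b)
    out: list[Span] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: Sequence[Span], b: Sequence[Span]) -> list[Span]:
    """Base pairs in both ``a`` and ``b``."""
    a = merge(a)
    b = merge(b)
    out: list[Span] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(spans: Iterable[Span]) -> int:
    """Total bp covered by the union of ``spans``."""
    return sum(e - s for s, e in merge(spans))


def covers(spans: Sequence[Span], pos: int) -> bool:
    """True if position ``pos`` lies inside the union of ``spans``."""
    return any(s <= pos < e for s, e in spans)


def offset_in(spans: Sequence[Span], pos: float, strand: str) -> float:
    """5'-wise offset of ``pos`` inside a disjoint sorted span list.

    For ``+`` strand the offset counts from the leftmost base; for ``-`` from
    the rightmost. ``pos`` may be fractional (interval midpoints). Raises
    ``ValueError`` when ``pos`` falls outside the spans.
    """
    acc = 0.0
    if strand == "-":
        for s, e in reversed(spans):
            if s <= pos < e or (pos == e and pos > s):
                return acc + (e - pos)
            acc += e - s
    else:
        for s, e in spans:
            if s <= pos < e or (pos == e and pos > s):
                return acc + (pos - s)
            acc += e - s
    raise ValueError(f"position {pos} outside spans")
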