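"""Readers and writers for the formats the pipeline consumes and emits.

GTF (GENCODE attribute dialect), gene FASTA, BED6, snoGloBe-style window-score
TSV, DESeq2-style differential-expression result tables, and GMT gene-set
collections. GTF coordinates are converted between the file convention
(1-based, closed) and the package convention (0-based, half-open) on
read/write. All writers are byte-deterministic for identical inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotationError, GeneModel, TranscriptModel
from .intervals import GenomicInterval

PathLike = Union[str, Path]


class GTFParseError(ValueError):
    """Malformed GTF content; the message names the offending line number."""


class SchemaError(ValueError):
    """A tabular input is missing required columns."""


class RowError(ValueError):
    """A tabular input row violates a field invariant."""


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_FEATURES = {"gene", "transcript", "exon", "CDS"}


def _parse_attributes(text: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for key, value in _ATTR_RE.findall(text):
        attrs.setdefault(key, []).append(value)
    return attrs


def _parse_tsl(value: Optional[str]) -> Optional[int]:
    if value is None:
        return None
    try:
        return int(value)
    except ValueError:
        return None  # "NA" and free-text TSL values count as missing


def read_gtf(path: PathLike) -> list[GeneModel]:
    """Read a GENCODE-dialect GTF into :class:`GeneModel` objects.

    Only ``gene``/``transcript``/``exon``/``CDS`` features are used. The
    ``transcript_support_level`` attribute is parsed to an int (absent or
    non-numeric values become missing) and ``basic`` is true when any ``tag``
    attribute equals ``"basic"``. Raises :class:`GTFParseError` naming the
    line number on malformed lines, :class:`AnnotationError` on exons or
    transcripts without a parent feature.
    """
    gene_meta: dict[str, dict] = {}
    tx_meta: dict[str, dict] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in _FEATURES:
                continue
            try:
                start = int(start_s) - 1  # GTF is 1-based closed
                end = int(end_s)
            except ValueError:
                raise GTFParseError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if not (0 <= start < end):
                raise GTFParseError(f"line {lineno}: invalid span {start_s}-{end_s}")
            attrs = _parse_attributes(attr_s)
            if "gene_id" not in attrs:
                raise GTFParseError(f"line {lineno}: missing gene_id attribute")
            gene_id = attrs["gene_id"][0]
            if feature == "gene":
                gene_meta[gene_id] = {
                    "symbol": attrs.get("gene_name", [""])[0],
                    "biotype": attrs.get("gene_type", [""])[0],
                }
                gene_order.append(gene_id)
                continue
            if "transcript_id" not in attrs:
                raise GTFParseError(f"line {lineno}: missing transcript_id attribute")
            tx_id = attrs["transcript_id"][0]
            if feature == "transcript":
                tx_meta[tx_id] = {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "support_level": _parse_tsl(
                        attrs.get("transcript_support_level", [None])[0]
                    ),
                    "basic": "basic" in attrs.get("tag", []),
                }
            elif feature == "exon":
                tx_exons.setdefault(tx_id, []).append((start, end))
            else:  # CDS
                tx_cds.setdefault(tx_id, []).append((start, end))

    for tx_id in set(tx_exons) | set(tx_cds):
        if tx_id not in tx_meta:
            raise AnnotationError(
                f"exon/CDS features reference transcript {tx_id} "
                "with no transcript feature"
            )

    genes_tx: dict[str, list[TranscriptModel]] = {}
    for tx_id, meta in tx_meta.items():
        if meta["gene_id"] not in gene_meta:
            raise AnnotationError(
                f"transcript {tx_id} references gene {meta['gene_id']} "
                "with no gene feature"
            )
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=meta["gene_id"],
            chrom=meta["chrom"],
            strand=meta["strand"],
            exons=tuple(tx_exons.get(tx_id, ())),
            cds=tuple(tx_cds.get(tx_id, ())),
            support_level=meta["support_level"],
            basic=meta["basic"],
        )
        genes_tx.setdefault(meta["gene_id"], []).append(model)

    genes = []
    for gene_id in gene_order:
        if gene_id not in genes_tx:
            continue  # gene with no transcript features: skipped
        txs = tuple(
            sorted(genes_tx[gene_id], key=lambda t: (t.span, t.transcript_id))
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                transcripts=txs,
                symbol=gene_meta[gene_id]["symbol"],
                biotype=gene_meta[gene_id]["biotype"],
            )
        )
    return genes


def write_gtf(genes: Sequence[GeneModel], path: PathLike) -> None:
    """Write gene models as GENCODE-dialect GTF (1-based closed coordinates)."""
    lines: list[str] = []

    def row(chrom, feature, start, end, strand, attrs):
        attr_s = " ".join(f'{k} "{v}";' for k, v in attrs)
        lines.append(
            "\t".join(
                [chrom, "snordpipe", feature, str(start + 1), str(end), ".", strand, ".", attr_s]
            )
        )

    for gene in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
        span = gene.span
        row(
            gene.chrom,
            "gene",
            span.start,
            span.end,
            gene.strand,
            [("gene_id", gene.gene_id), ("gene_name", gene.symbol), ("gene_type", gene.biotype)],
        )
        for tx in sorted(gene.transcripts, key=lambda t: (t.span, t.transcript_id)):
            tsl = "NA" if tx.support_level is None else str(tx.support_level)
            attrs = [
                ("gene_id", gene.gene_id),
                ("transcript_id", tx.transcript_id),
                ("transcript_support_level", tsl),
            ]
            if tx.basic:
                attrs.append(("tag", "basic"))
            s, e = tx.span
            row(gene.chrom, "transcript", s, e, tx.strand, attrs)
            base = [("gene_id", gene.gene_id), ("transcript_id", tx.transcript_id)]
            for s, e in tx.exons:
                row(gene.chrom, "exon", s, e, tx.strand, base)
            for s, e in tx.cds:
                row(gene.chrom, "CDS", s, e, tx.strand, base)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Window-score tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowScore:
    """One sliding-window snoRNA-target interaction score."""

    sno_id: str
    sno_start: int
    target_gene_id: str
    target_chrom: str
    target_start: int
    strand: str
    score: float
    window_length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise RowError(f"score {self.score} outside [0, 1]")
        if self.window_length <= 0:
            raise RowError("window_length must be positive")
        if self.strand not in ("+", "-"):
            raise RowError("window scores must be stranded (+/-)")


#: canonical column name -> default file column name
DEFAULT_WINDOW_COLUMNS: dict[str, str] = {
    "sno_id": "sno_id",
    "sno_start": "sno_window_start",
    "target_gene_id": "target_id",
    "target_chrom": "target_chrom",
    "target_start": "target_window_start",
    "strand": "strand",
    "score": "score",
}

#: snoGloBe-like sliding-window width, nt (configurable per table)
DEFAULT_WINDOW_LENGTH = 13


def read_window_scores(
    path: PathLike,
    column_map: Optional[Mapping[str, str]] = None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
) -> pd.DataFrame:
    """Read a window-score TSV into a canonical-column DataFrame.

    ``column_map`` maps canonical names (keys of
    :data:`DEFAULT_WINDOW_COLUMNS`) to the file's column names. The returned
    frame has the canonical columns and carries ``window_length`` in
    ``DataFrame.attrs``. Scores outside [0, 1], non-numeric scores and
    unstranded rows are rejected.
    """
    cmap = dict(DEFAULT_WINDOW_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cmap["sno_id"]: str})
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"window-score table missing columns: {', '.join(missing)}")
    df = df.rename(columns={v: k for k, v in cmap.items()})[list(cmap)]
    score = pd.to_numeric(df["score"], errors="coerce")
    bad = df.index[score.isna() | (score < 0) | (score > 1)]
    if len(bad):
        raise RowError(
            f"invalid score in row(s) {', '.join(str(i) for i in bad[:5])}"
            + (" ..." if len(bad) > 5 else "")
        )
    df["score"] = score.astype(float)
    bad_strand = df.index[~df["strand"].isin(["+", "-"])]
    if len(bad_strand):
        raise RowError(f"unstranded/invalid strand in row(s) {list(bad_strand[:5])}")
    df["sno_start"] = df["sno_start"].astype(int)
    df["target_start"] = df["target_start"].astype(int)
    df.attrs["window_length"] = int(window_length)
    return df.reset_index(drop=True)


def write_window_scores(
    df: pd.DataFrame,
    path: PathLike,
    column_map: Optional[Mapping[str, str]] = None,
) -> None:
    cmap = dict(DEFAULT_WINDOW_COLUMNS)
    if column_map:
        cmap.update(column_map)
    out = df[list(cmap)].rename(columns=cmap)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed(
    records: Iterable[tuple[GenomicInterval, str, float]],
    path: PathLike,
) -> None:
    """Write (interval, name, score) records as BED6.

    Scores are rounded and clamped to the BED integer range [0, 1000]; rows
    are sorted by (chrom, start, end, name) for byte determinism.
    """
    rows = []
    for iv, name, score in records:
        clamped = max(0, min(1000, int(round(score))))
        rows.append((iv.chrom, iv.start, iv.end, name, clamped, iv.strand))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_bed(path: PathLike) -> list[tuple[GenomicInterval, str, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise GTFParseError(f"BED line {lineno}: expected 6 fields")
            out.append(
                (GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]), f[3], int(f[4]))
            )
    return out


# ---------------------------------------------------------------------------
# Differential-expression result tables
# ---------------------------------------------------------------------------

_DE_ALIASES = {
    "gene_id": ["gene_id", "gene", "ensembl_id", "id"],
    "baseMean": ["basemean"],
    "log2FoldChange": ["log2foldchange", "log2fc", "lfc"],
    "pvalue": ["pvalue", "p_value", "pval"],
    "padj": ["padj", "p_adj", "qvalue", "fdr"],
}


def read_de_table(path: PathLike) -> pd.DataFrame:
    """Read a DESeq2-style results TSV.

    Accepts the gene identifier as a named column or as an unnamed first
    (row-name) column, and common header spellings of baseMean /
    log2FoldChange / pvalue / padj.
    """
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canon, aliases in _DE_ALIASES.items():
        for a in [canon.lower()] + aliases:
            if a in lower:
                rename[lower[a]] = canon
                break
    df = df.rename(columns=rename)
    if "gene_id" not in df.columns:
        first = df.columns[0]
        if first.startswith("Unnamed") or first == "":
            df = df.rename(columns={first: "gene_id"})
    required = ["gene_id", "baseMean", "log2FoldChange", "pvalue", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"DE table missing columns: {', '.join(missing)}")
    return df[required]


def write_de_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: PathLike) -> dict[str, list[str]]:
    """Read a GMT file: ``set_name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"GMT line {lineno}: expected >= 3 fields")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
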