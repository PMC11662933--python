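"""Positional profiling of predicted binding events.

snoRNA side: where along each copy (relative 0-1 coordinates, with the
C/D'/C'/D boxes overlaid) the centers of merged binding events fall — for
group III the mass is expected between the C' and D boxes (the ASE2 guide
segment). Target side: bedtools-style feature coverage (exon / intron /
exon-intron junction, with exonic events subdivided into 5'UTR / CDS / 3'UTR
and their straddles) over the union of retained transcripts, and a metagene
density where [0,1) is the 5'UTR, [1,2) the gene body and [2,3) the 3'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genome import TranscriptModel
from .intervals import (
    GenomicInterval,
    Span,
    intersect,
    merge,
    offset_in,
    subtract,
    total_length,
)
from .interactions import Interaction
from .snorna import SnoRNACopy, registry_index

TIER1 = ("exon", "intron", "junction")
TIER2 = ("utr5", "utr3", "cds", "utr5+cds", "utr3+cds", "other")


# ---------------------------------------------------------------------------
# snoRNA-side relative positions
# ---------------------------------------------------------------------------

@dataclass
class SnoPositionProfile:
    group: str
    positions: np.ndarray  # relative center positions, one per interaction
    bin_edges: np.ndarray
    histogram: np.ndarray  # counts; total mass = number of interactions
    box_overlay: dict[str, tuple[float, float]]  # group-mean relative box spans


def _group_label(copy: SnoRNACopy) -> str:
    return copy.group if copy.group is not None else copy.cluster


def sno_relative_positions(
    interactions: Iterable[Interaction],
    registry: Sequence[SnoRNACopy],
    bin_width: float = 0.01,
) -> dict[str, SnoPositionProfile]:
    """Histogram of event centers along the snoRNA, per copy group.

    The center is the floored midpoint of the event's snoRNA interval; its
    relative position is center / copy length. The box overlay is the
    per-group mean of each box's (start/L, end/L). Groups with no events
    still emit their overlay with an empty histogram.
    """
    reg = registry_index(registry)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    by_group: dict[str, list[float]] = {}
    for copy in registry:
        by_group.setdefault(_group_label(copy), [])
    for x in interactions:
        copy = reg[x.sno_id]
        rel = x.sno_center / copy.length
        by_group[_group_label(copy)].append(rel)

    profiles: dict[str, SnoPositionProfile] = {}
    for group, positions in by_group.items():
        copies = [c for c in registry if _group_label(c) == group]
        overlay = {}
        for box in ("box_c", "box_dprime", "box_cprime", "box_d"):
            rel_spans = [
                (getattr(c, box)[0] / c.length, getattr(c, box)[1] / c.length)
                for c in copies
            ]
            overlay[box] = (
                float(np.mean([s for s, _ in rel_spans])),
                float(np.mean([e for _, e in rel_spans])),
            )
        pos = np.asarray(positions, dtype=float)
        hist, _ = np.histogram(pos, bins=edges)
        profiles[group] = SnoPositionProfile(
            group=group,
            positions=pos,
            bin_edges=edges,
            histogram=hist,
            box_overlay=overlay,
        )
    return profiles


# ---------------------------------------------------------------------------
# target-side feature space
# ---------------------------------------------------------------------------

@dataclass
class GeneFeatureSpace:
    """Per-gene labeled bp space built from retained transcripts."""

    gene_id: str
    chrom: str
    strand: str
    exon: list[Span]  # union of retained-transcript exons
    intron: list[Span]  # union of per-transcript introns, minus exonic bp
    tier2: dict[str, list[Span]]  # utr5/cds/utr3/other partition of exon space


@dataclass
class FeatureCoverageProfile:
    basis: str  # "background" (bp) or "events" (interval counts)
    tier1: dict[str, float]  # fractions over exon/intron/junction
    tier2: dict[str, float]  # fractions over exonic mass
    n_unassigned: int = 0


def build_feature_space(
    retained: Mapping[str, Sequence[TranscriptModel]],
) -> dict[str, GeneFeatureSpace]:
    """Label each gene's bp space from its retained transcripts.

    Exon space is the union of exons; intron space the union of per-
    transcript introns minus exonic bp. Exonic bp get a 5'UTR/CDS/3'UTR
    label by majority vote of the retained transcripts whose exons cover the
    bp (ties resolved toward CDS; bp covered only by non-coding transcripts
    are "other").
    """
    spaces: dict[str, GeneFeatureSpace] = {}
    for gene_id, txs in retained.items():
        exon = merge(sp for t in txs for sp in t.exons)
        intron_union = merge(sp for t in txs for sp in t.introns)
        intron = subtract(intron_union, exon)
        tier2 = _vote_tier2(txs, exon)
        spaces[gene_id] = GeneFeatureSpace(
            gene_id=gene_id,
            chrom=txs[0].chrom,
            strand=txs[0].strand,
            exon=exon,
            intron=intron,
            tier2=tier2,
        )
    return spaces


def _vote_tier2(
    txs: Sequence[TranscriptModel], exon: list[Span]
) -> dict[str, list[Span]]:
    bounds: set[int] = set()
    for s, e in exon:
        bounds.update((s, e))
    per_tx: list[dict[str, list[Span]]] = []
    for t in txs:
        regions = {"utr5": list(t.utr5), "cds": list(t.cds), "utr3": list(t.utr3)}
        per_tx.append(regions)
        for spans in regions.values():
            for s, e in spans:
                bounds.update((s, e))
        for s, e in t.exons:
            bounds.update((s, e))
    cuts = sorted(bounds)
    out: dict[str, list[Span]] = {k: [] for k in ("utr5", "cds", "utr3", "other")}
    for s, e in zip(cuts, cuts[1:]):
        if not intersect(exon, [(s, e)]):
            continue
        votes = {"utr5": 0, "cds": 0, "utr3": 0}
        covered_noncoding = 0
        for t, regions in zip(txs, per_tx):
            if not intersect(list(t.exons), [(s, e)]):
                continue
            hit = None
            for label, spans in regions.items():
                if intersect(spans, [(s, e)]):
                    hit = label
                    break
            if hit is None:
                covered_noncoding += 1
            else:
                votes[hit] += 1
        if sum(votes.values()) == 0:
            label = "other"
        else:
            best = max(votes.values())
            winners = [k for k, v in votes.items() if v == best]
            label = "cds" if "cds" in winners and (len(winners) > 1) else winners[0]
        out[label].append((s, e))
    return {k: merge(v) for k, v in out.items()}


def background_profile(spaces: Mapping[str, GeneFeatureSpace]) -> FeatureCoverageProfile:
    """bp-fraction feature coverage of the gene space itself (Fig-4D-style
    background basis): exon vs intron bp (junctions are interval-level and
    carry no bp mass), with exonic bp split by tier-2 label."""
    exon_bp = sum(total_length(s.exon) for s in spaces.values())
    intron_bp = sum(total_length(s.intron) for s in spaces.values())
    total = exon_bp + intron_bp
    tier2_bp = {k: 0 for k in ("utr5", "utr3", "cds", "other")}
    for s in spaces.values():
        for k, spans in s.tier2.items():
            tier2_bp[k] += total_length(spans)
    tier1 = {
        "exon": exon_bp / total if total else 0.0,
        "intron": intron_bp / total if total else 0.0,
        "junction": 0.0,
    }
    tier2 = {k: (v / exon_bp if exon_bp else 0.0) for k, v in tier2_bp.items()}
    tier2.update({"utr5+cds": 0.0, "utr3+cds": 0.0})
    return FeatureCoverageProfile(basis="background", tier1=tier1, tier2=tier2)


def classify_interval(
    iv: GenomicInterval, space: GeneFeatureSpace
) -> tuple[Optional[str], Optional[str]]:
    """(tier1, tier2) labels for one interval against one gene's space.

    tier1: exon / intron / junction, or None when the interval touches
    neither space. tier2 is set for exonic intervals only: the single
    overlapped subspace, "utr5+cds" / "utr3+cds" for those straddles, or
    "other" for any other combination.
    """
    span = [(iv.start, iv.end)]
    in_exon = bool(intersect(space.exon, span))
    in_intron = bool(intersect(space.intron, span))
    if in_exon and in_intron:
        return "junction", None
    if in_intron:
        return "intron", None
    if not in_exon:
        return None, None
    hit = {k for k, spans in space.tier2.items() if intersect(spans, span)}
    if len(hit) == 1:
        t2 = hit.pop()
    elif hit == {"utr5", "cds"}:
        t2 = "utr5+cds"
    elif hit == {"utr3", "cds"}:
        t2 = "utr3+cds"
    else:
        t2 = "other"
    return "exon", t2


def classify_intervals(
    events: Sequence[tuple[GenomicInterval, str]],
    spaces: Mapping[str, GeneFeatureSpace],
) -> tuple[FeatureCoverageProfile, list[tuple[GenomicInterval, str]]]:
    """Feature-coverage profile of (interval, gene_id) events.

    Events on genes missing from the space, or overlapping neither exon nor
    intron bp, go to an explicit unassigned bucket (returned, and counted in
    the profile's ``n_unassigned``) rather than being dropped silently.
    """
    tier1_counts = {k: 0 for k in TIER1}
    tier2_counts = {k: 0 for k in TIER2}
    unassigned: list[tuple[GenomicInterval, str]] = []
    for iv, gene_id in events:
        space = spaces.get(gene_id)
        t1 = t2 = None
        if space is not None:
            t1, t2 = classify_interval(iv, space)
        if t1 is None:
            unassigned.append((iv, gene_id))
            continue
        tier1_counts[t1] += 1
        if t2 is not None:
            tier2_counts[t2] += 1
    n1 = sum(tier1_counts.values())
    n2 = sum(tier2_counts.values())
    return (
        FeatureCoverageProfile(
            basis="events",
            tier1={k: (v / n1 if n1 else 0.0) for k, v in tier1_counts.items()},
            tier2={k: (v / n2 if n2 else 0.0) for k, v in tier2_counts.items()},
            n_unassigned=len(unassigned),
        ),
        unassigned,
    )


# ---------------------------------------------------------------------------
# metagene mapping
# ---------------------------------------------------------------------------

@dataclass
class MetageneDensity:
    bin_edges: np.ndarray  # over [0, 3)
    curves: dict[str, np.ndarray]  # per group + "overall"; each integrates to 1
    weights: dict[str, float]  # total mapped event weight per curve


def _metagene_coord(
    midpoint: float, tx: TranscriptModel
) -> Optional[float]:
    """Map a genomic midpoint to the [0,3) metagene axis for one transcript.

    Coding transcripts: 5'UTR -> [0,1), CDS (gene body) -> [1,2),
    3'UTR -> [2,3); non-coding transcripts map their whole exonic span to
    the gene body. Returns None when the midpoint misses the transcript's
    regions (e.g. intronic for this transcript).
    """
    regions: list[tuple[float, tuple[Span, ...]]]
    if tx.is_coding:
        regions = [(0.0, tx.utr5), (1.0, tx.cds), (2.0, tx.utr3)]
    else:
        regions = [(1.0, tx.exons)]
    for base, spans in regions:
        spans = tuple(spans)
        if not spans:
            continue
        lo = spans[0][0]
        hi = spans[-1][1]
        if not (lo <= midpoint < hi):
            continue
        try:
            off = offset_in(spans, midpoint, tx.strand)
        except ValueError:
            continue  # in a gap between this region's spans
        return base + off / total_length(spans)
    return None


def metagene_density(
    events: Sequence[tuple[GenomicInterval, str, str]],
    retained: Mapping[str, Sequence[TranscriptModel]],
    n_bins: int = 60,
) -> MetageneDensity:
    """Metagene density of event midpoints, per snoRNA group plus overall.

    ``events`` rows are (target interval, target gene id, group label). Each
    event's (fractional) midpoint is mapped per retained transcript of its
    gene and the event's unit weight is split evenly over the transcripts
    that map it; densities are normalized to integrate to 1.
    """
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    coords: dict[str, list[float]] = {"overall": []}
    weights: dict[str, list[float]] = {"overall": []}
    for iv, gene_id, group in events:
        txs = retained.get(gene_id, ())
        mid = (iv.start + iv.end) / 2.0
        mapped = [c for c in (_metagene_coord(mid, t) for t in txs) if c is not None]
        if not mapped:
            continue
        w = 1.0 / len(mapped)
        for key in (group, "overall"):
            coords.setdefault(key, [])
            weights.setdefault(key, [])
            coords[key].extend(mapped)
            weights[key].extend([w] * len(mapped))
    curves: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    bin_width = 3.0 / n_bins
    for key, cs in coords.items():
        hist, _ = np.histogram(cs, bins=edges, weights=weights[key])
        total = float(hist.sum())
        totals[key] = total
        curves[key] = hist / (total * bin_width) if total > 0 else hist
    return MetageneDensity(bin_edges=edges, curves=curves, weights=totals)
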