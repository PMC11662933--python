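"""Feature-space labeling vs a per-base oracle; metagene and sno-side maps."""

import numpy as np
import pytest

from snordpipe.genome import GeneModel, TranscriptModel, filter_transcripts
from snordpipe.intervals import GenomicInterval, total_length
from snordpipe.interactions import FilterParams, Interaction, merge_consecutive_windows
from snordpipe.positional import (
    background_profile,
    build_feature_space,
    classify_interval,
    classify_intervals,
    metagene_density,
    sno_relative_positions,
)
from snordpipe.synthetic import build_toy_annotation, simulate_window_scores

from conftest import make_transcript


# ------------------------------------------------------------ per-base oracle

def per_base_labels(txs, span):
    """Brute-force bp labeling: returns (exon_mask, intron_mask, tier2 array)."""
    off, width = span
    n = width - off
    exon = np.zeros(n, dtype=bool)
    intron = np.zeros(n, dtype=bool)
    tier2 = np.full(n, "", dtype=object)
    for t in txs:
        for s, e in t.exons:
            exon[s - off : e - off] = True
        for s, e in t.introns:
            intron[s - off : e - off] = True
    intron &= ~exon
    for i in np.where(exon)[0]:
        pos = i + off
        votes = {"utr5": 0, "cds": 0, "utr3": 0}
        noncoding = 0
        for t in txs:
            if not any(s <= pos < e for s, e in t.exons):
                continue
            if any(s <= pos < e for s, e in t.utr5):
                votes["utr5"] += 1
            elif any(s <= pos < e for s, e in t.cds):
                votes["cds"] += 1
            elif any(s <= pos < e for s, e in t.utr3):
                votes["utr3"] += 1
            else:
                noncoding += 1
        if sum(votes.values()) == 0:
            tier2[i] = "other"
        else:
            best = max(votes.values())
            winners = [k for k, v in votes.items() if v == best]
            tier2[i] = "cds" if "cds" in winners and len(winners) > 1 else winners[0]
    return exon, intron, tier2


def test_feature_space_matches_per_base_oracle(annotation, retained):
    genes, _ = annotation
    spaces = build_feature_space(retained)
    for g in genes:
        if g.gene_id not in spaces:
            continue
        sp = spaces[g.gene_id]
        txs = retained[g.gene_id]
        lo = min(t.span[0] for t in txs)
        hi = max(t.span[1] for t in txs)
        exon, intron, tier2 = per_base_labels(txs, (lo, hi))
        assert total_length(sp.exon) == int(exon.sum())
        assert total_length(sp.intron) == int(intron.sum())
        for label in ("utr5", "cds", "utr3", "other"):
            assert total_length(sp.tier2[label]) == int((tier2 == label).sum()), (
                g.gene_id, label,
            )


def test_classification_matches_per_base_oracle(annotation, retained, rng):
    genes, _ = annotation
    spaces = build_feature_space(retained)
    for g in genes[:30]:
        if g.gene_id not in spaces:
            continue
        sp = spaces[g.gene_id]
        txs = retained[g.gene_id]
        lo = min(t.span[0] for t in txs)
        hi = max(t.span[1] for t in txs)
        exon, intron, tier2 = per_base_labels(txs, (lo, hi))
        for _ in range(20):
            s = int(rng.integers(lo, hi - 1))
            e = s + int(rng.integers(1, 30))
            t1, t2 = classify_interval(
                GenomicInterval(g.chrom, s, e, g.strand), sp
            )
            seg_e = exon[s - lo : min(e, hi) - lo]
            seg_i = intron[s - lo : min(e, hi) - lo]
            if seg_e.any() and seg_i.any():
                assert t1 == "junction"
            elif seg_i.any():
                assert t1 == "intron"
            elif seg_e.any():
                assert t1 == "exon"
                labels = set(tier2[s - lo : min(e, hi) - lo]) - {""}
                if len(labels) == 1:
                    assert t2 == labels.pop()
                elif labels == {"utr5", "cds"}:
                    assert t2 == "utr5+cds"
                elif labels == {"utr3", "cds"}:
                    assert t2 == "utr3+cds"
                else:
                    assert t2 == "other"
            else:
                assert t1 is None


# ------------------------------------------------------- aggregate profiles

def test_tier_fractions_sum_to_one(annotation, retained, rng):
    genes, _ = annotation
    spaces = build_feature_space(retained)
    bg = background_profile(spaces)
    assert sum(bg.tier1.values()) == pytest.approx(1.0, abs=1e-9)
    assert sum(bg.tier2.values()) == pytest.approx(1.0, abs=1e-9)
    events = []
    for g in genes[:20]:
        if g.gene_id not in spaces:
            continue
        s = g.span.start + int(rng.integers(0, max(1, g.span.width - 20)))
        events.append((GenomicInterval(g.chrom, s, s + 15, g.strand), g.gene_id))
    prof, unassigned = classify_intervals(events, spaces)
    assert sum(prof.tier1.values()) == pytest.approx(1.0, abs=1e-9)
    assert prof.n_unassigned == len(unassigned)


def test_unassigned_goes_to_explicit_bucket(retained):
    spaces = build_feature_space(retained)
    far = GenomicInterval("chr9", 1, 10, "+")
    prof, unassigned = classify_intervals([(far, "NOPE")], spaces)
    assert prof.n_unassigned == 1 and unassigned[0][1] == "NOPE"


# ---------------------------------------------------------------- metagene

def coding_tx(strand="+"):
    # exon [0,300); cds [100,200): utr5 and utr3 of 100 bp each
    return make_transcript(
        exons=((0, 300),), cds=((100, 200),), strand=strand
    )


@pytest.mark.parametrize("strand", ["+", "-"])
def test_metagene_landmark_coordinates(strand):
    tx = coding_tx(strand)
    retained = {"G1": [tx]}
    chrom = "chr1"
    if strand == "+":
        half_utr5 = GenomicInterval(chrom, 49, 51, strand)  # midpoint 50
        cds_start = GenomicInterval(chrom, 99, 101, strand)  # midpoint 100
        half_utr3 = GenomicInterval(chrom, 249, 251, strand)  # midpoint 250
    else:
        half_utr5 = GenomicInterval(chrom, 249, 251, strand)
        cds_start = GenomicInterval(chrom, 199, 201, strand)
        half_utr3 = GenomicInterval(chrom, 49, 51, strand)
    events = [
        (half_utr5, "G1", "III"),
        (cds_start, "G1", "III"),
        (half_utr3, "G1", "III"),
    ]
    md = metagene_density(events, retained, n_bins=60)
    # recover the mapped coordinates from the histogram bin centers
    centers = (md.bin_edges[:-1] + md.bin_edges[1:]) / 2
    hit = centers[md.curves["overall"] > 0]
    assert np.allclose(sorted(hit), [0.525, 1.025, 2.525], atol=0.026)


def test_metagene_density_integrates_to_one(annotation, retained, rng):
    genes, _ = annotation
    events = []
    for g in genes:
        if g.gene_id not in retained:
            continue
        for _ in range(3):
            s = g.span.start + int(rng.integers(0, max(1, g.span.width - 15)))
            events.append(
                (GenomicInterval(g.chrom, s, s + 13, g.strand), g.gene_id, "III")
            )
    md = metagene_density(events, retained)
    bw = md.bin_edges[1] - md.bin_edges[0]
    for key, curve in md.curves.items():
        if md.weights[key] > 0:
            assert curve.sum() * bw == pytest.approx(1.0, abs=1e-6)


def mirror_annotation(genes, L):
    """Mirror every coordinate x -> L - x and flip strands."""
    def flip_spans(spans):
        return tuple(sorted((L - e, L - s) for s, e in spans))

    out = []
    for g in genes:
        txs = []
        for t in g.transcripts:
            txs.append(
                TranscriptModel(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    chrom=t.chrom,
                    strand="-" if t.strand == "+" else "+",
                    exons=flip_spans(t.exons),
                    cds=flip_spans(t.cds),
                    support_level=t.support_level,
                    basic=t.basic,
                )
            )
        out.append(GeneModel(gene_id=g.gene_id, transcripts=tuple(txs)))
    return out


def test_strand_mirroring_leaves_profiles_unchanged(annotation, retained, rng):
    genes, _ = annotation
    L = 10_000_000
    mirrored = mirror_annotation(genes, L)
    retained_m, _ = filter_transcripts(mirrored)
    events, events_m = [], []
    for g, gm in zip(genes, mirrored):
        if g.gene_id not in retained:
            continue
        for _ in range(3):
            s = g.span.start + int(rng.integers(0, max(1, g.span.width - 15)))
            events.append(
                (GenomicInterval(g.chrom, s, s + 13, g.strand), g.gene_id, "III")
            )
            events_m.append(
                (
                    GenomicInterval(g.chrom, L - (s + 13), L - s, gm.strand),
                    g.gene_id,
                    "III",
                )
            )
    md = metagene_density(events, retained)
    md_m = metagene_density(events_m, retained_m)
    np.testing.assert_allclose(md.curves["overall"], md_m.curves["overall"])
    # interval classification is mirror-invariant too
    spaces = build_feature_space(retained)
    spaces_m = build_feature_space(retained_m)
    for (iv, gid, _), (ivm, _, _) in zip(events, events_m):
        assert classify_interval(iv, spaces[gid]) == classify_interval(
            ivm, spaces_m[gid]
        )


# ------------------------------------------------------------- snoRNA side

def test_sno_relative_center_position(registry):
    copy = next(c for c in registry if c.length == 100) if any(
        c.length == 100 for c in registry
    ) else registry[0]
    x = Interaction(
        sno_id=copy.copy_id,
        sno_start=40,
        sno_end=50,
        target_gene_id="G1",
        target=GenomicInterval("chr1", 0, 10, "+"),
        n_windows=3,
        min_score=0.99,
        mean_score=0.99,
    )
    profs = sno_relative_positions([x], [copy])
    grp = copy.group if copy.group else copy.cluster
    assert profs[grp].positions[0] == pytest.approx(45 / copy.length)
    assert profs[grp].histogram.sum() == 1


def test_sno_profiles_emitted_even_without_events(registry):
    profs = sno_relative_positions([], registry)
    assert set(profs) == {"I", "II", "III", "SNORD115"}
    for p in profs.values():
        assert p.histogram.sum() == 0
        c = p.box_overlay
        assert c["box_c"][0] < c["box_dprime"][0] < c["box_cprime"][0] < c["box_d"][0]


def test_ase2_planted_events_peak_between_cprime_and_d(registry):
    genes, _ = build_toy_annotation(30, seed=55)
    retained, _ = filter_transcripts(genes)
    targets = [g.gene_id for g in genes[:12]]
    windows, _ = simulate_window_scores(
        registry, genes, retained, targets,
        background_event_rate=3.0, p_ase2=1.0, seed=56,
    )
    inter = merge_consecutive_windows(windows, FilterParams())
    profs = sno_relative_positions(inter, registry)
    for grp, prof in profs.items():
        if len(prof.positions) < 10:
            continue
        mode_bin = prof.histogram.argmax()
        mode = (prof.bin_edges[mode_bin] + prof.bin_edges[mode_bin + 1]) / 2
        assert prof.box_overlay["box_cprime"][1] <= mode <= prof.box_overlay["box_d"][0] + 0.02
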