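"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates every input the analysis consumes — a toy annotation with
sequences, negative-binomial count matrices for the 2-background x 3-genotype
isogenic design, parametric differential-expression result tables with
controlled per-design power, and snoGloBe-style window-score tables with
planted high-score runs — together with a truth table indexing every planted
effect, so recovery can be measured exactly.

The DE tables are generated parametrically from the truth (the DE engine
itself is out of scope here); an emulation of a negative-binomial GLM fit is
deliberately not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, TranscriptModel
from .intervals import Span
from .snorna import SnoRNACopy, registry_index

BACKGROUNDS = ("H9", "CT2")
GENOTYPES = ("WT", "smDEL", "lgDEL")
MODELS = ("smDEL", "lgDEL")
#: the three per-deletion statistical designs whose results are intersected:
#: cross-background-reproducible pairwise analysis, the background-interaction
#: design, and the condition-only design
DESIGNS = ("crossbg", "interaction", "condition")

_BASES_AT = np.array(list("AT"))
_BASES_GC = np.array(list("GC"))


# ---------------------------------------------------------------------------
# annotation + sequences
# ---------------------------------------------------------------------------

def build_toy_annotation(
    n_genes: int,
    n_chroms: int = 2,
    gc_targets: float | Sequence[float] = 0.45,
    seed: int = 0,
    coding_fraction: float = 0.85,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Generate a toy annotation and per-gene (span) sequences.

    Genes carry 1-3 transcripts and 1-8 exons; each gene's first transcript
    uses all exons, has TSL 1-3 and the basic tag (so every gene survives the
    standard transcript filter); additional transcripts draw mixed TSL
    1-5/missing and basic flags. Coding transcripts get a CDS strictly inside
    their exon space, yielding non-empty 5'/3' UTRs. Sequences realize the
    requested GC fraction exactly (to rounding) by construction.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    gc = np.broadcast_to(np.asarray(gc_targets, dtype=float), (n_genes,))
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("gc_targets must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    genes: list[GeneModel] = []
    sequences: dict[str, str] = {}
    cursor = {f"chr{c + 1}": 1000 for c in range(n_chroms)}
    for i in range(n_genes):
        gene_id = f"GENE{i + 1:05d}"
        chrom = f"chr{(i % n_chroms) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 9))
        exon_lens = rng.integers(80, 400, size=n_exons)
        intron_lens = rng.integers(40, 300, size=max(0, n_exons - 1))
        start = cursor[chrom]
        exons: list[Span] = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        gene_end = exons[-1][1]
        cursor[chrom] = gene_end + int(rng.integers(500, 2000))

        coding = rng.random() < coding_fraction
        transcripts = [
            _make_transcript(
                f"{gene_id}.T1", gene_id, chrom, strand, exons, coding,
                tsl=int(rng.integers(1, 4)), basic=True, rng=rng,
            )
        ]
        for extra in range(int(rng.integers(0, 3))):
            lo = int(rng.integers(0, n_exons))
            hi = int(rng.integers(lo + 1, n_exons + 1))
            sub = exons[lo:hi]
            tsl_draw = rng.integers(1, 7)
            transcripts.append(
                _make_transcript(
                    f"{gene_id}.T{extra + 2}", gene_id, chrom, strand, sub,
                    coding and rng.random() < 0.7,
                    tsl=None if tsl_draw == 6 else int(tsl_draw),
                    basic=bool(rng.random() < 0.6),
                    rng=rng,
                )
            )
        gene = GeneModel(
            gene_id=gene_id,
            transcripts=tuple(transcripts),
            symbol=f"SYN{i + 1}",
            biotype="protein_coding" if coding else "lncRNA",
        )
        genes.append(gene)
        sequences[gene_id] = _sequence_with_gc(
            gene.span.width, float(gc[i]), rng
        )
    return genes, sequences


def _make_transcript(
    tx_id: str,
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Sequence[Span],
    coding: bool,
    tsl: Optional[int],
    basic: bool,
    rng: np.random.Generator,
) -> TranscriptModel:
    cds: tuple[Span, ...] = ()
    if coding:
        # CDS bounded strictly inside exonic space so both UTRs are non-empty
        exonic = sum(e - s for s, e in exons)
        if exonic >= 150:
            a = int(rng.integers(int(0.10 * exonic), int(0.35 * exonic)))
            b = int(rng.integers(int(0.60 * exonic), int(0.90 * exonic)))
            cds = tuple(_exonic_slice(exons, a, b))
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds=cds,
        support_level=tsl,
        basic=basic,
    )


def _exonic_slice(exons: Sequence[Span], a: int, b: int) -> list[Span]:
    """Genomic spans of exonic offsets [a, b) (offsets count leftmost-first)."""
    out: list[Span] = []
    acc = 0
    for s, e in exons:
        w = e - s
        lo = max(a, acc)
        hi = min(b, acc + w)
        if lo < hi:
            out.append((s + lo - acc, s + hi - acc))
        acc += w
    return out


def _sequence_with_gc(length: int, gc: float, rng: np.random.Generator) -> str:
    n_gc = int(round(gc * length))
    bases = np.concatenate(
        [
            _BASES_GC[rng.integers(0, 2, size=n_gc)],
            _BASES_AT[rng.integers(0, 2, size=length - n_gc)],
        ]
    )
    rng.shuffle(bases)
    return "".join(bases)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample design metadata."""

    counts: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # index: sample id; columns: background, genotype, replicate
    size_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("sample metadata must cover every count column")

    def normalized(self) -> pd.DataFrame:
        """Library-size normalized counts (scaled to the mean library size).

        Samples with an empty library keep their (all-zero) counts.
        """
        lib = self.counts.sum(axis=0)
        mean_lib = lib[lib > 0].mean()
        factors = (lib / mean_lib).where(lib > 0, 1.0) if lib.gt(0).any() else 1.0
        return self.counts / factors


def make_truth_table(
    gene_ids: Sequence[str],
    n_shared_up: int = 25,
    n_shared_down: int = 25,
    n_background_specific: int = 50,
    effect_size: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign planted statuses to genes and record true per-model log2FCs.

    Shared genes are perturbed in both backgrounds and both deletion models;
    background-specific genes in exactly one background (both models); the
    rest are null. ``is_planted_target`` starts false and is set by the
    window-score planting step.
    """
    n = len(gene_ids)
    n_planted = n_shared_up + n_shared_down + n_background_specific
    if n_planted > n:
        raise ValueError("more planted genes than genes available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    status = np.array(["null"] * n, dtype=object)
    lfc = np.zeros(n)
    specific_bg = np.array([""] * n, dtype=object)
    i = 0
    status[order[i : i + n_shared_up]] = "shared_up"
    lfc[order[i : i + n_shared_up]] = effect_size
    i += n_shared_up
    status[order[i : i + n_shared_down]] = "shared_down"
    lfc[order[i : i + n_shared_down]] = -effect_size
    i += n_shared_down
    spec = order[i : i + n_background_specific]
    status[spec] = "background_specific"
    lfc[spec] = effect_size * rng.choice([-1.0, 1.0], size=len(spec))
    specific_bg[spec] = rng.choice(list(BACKGROUNDS), size=len(spec))
    return pd.DataFrame(
        {
            "status": status,
            "lfc_smDEL": lfc,
            "lfc_lgDEL": lfc,
            "specific_background": specific_bg,
            "is_planted_target": False,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def simulate_counts(
    gene_ids: Sequence[str],
    truth: pd.DataFrame,
    n_reps: int = 6,
    mu_range: tuple[float, float] = (20.0, 2000.0),
    dispersion: float = 0.05,
    size_factor_range: tuple[float, float] = (0.7, 1.3),
    seed: int = 0,
) -> CountMatrix:
    """Negative-binomial counts for the 2-background x 3-genotype design.

    Per-gene baseline means are log-uniform over ``mu_range``; variance
    follows mu + dispersion * mu^2. Planted genes are perturbed by their true
    log2FC in the deletion genotypes of the backgrounds their status covers.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    mu0 = np.exp(rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]), size=n))

    sample_rows = []
    for bg in BACKGROUNDS:
        for gt in GENOTYPES:
            for r in range(1, n_reps + 1):
                sample_rows.append((f"{bg}_{gt}_{r}", bg, gt, r))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "background", "genotype", "replicate"]
    ).set_index("sample_id")
    sf = pd.Series(
        rng.uniform(*size_factor_range, size=len(samples)), index=samples.index
    )

    truth = truth.loc[list(gene_ids)]
    status = truth["status"].to_numpy()
    spec_bg = truth["specific_background"].to_numpy()
    nb_n = 1.0 / dispersion
    cols = {}
    for sid, row in samples.iterrows():
        lfc = np.zeros(n)
        if row["genotype"] != "WT":
            model_lfc = truth[f"lfc_{row['genotype']}"].to_numpy()
            shared = np.isin(status, ["shared_up", "shared_down"])
            specific = (status == "background_specific") & (spec_bg == row["background"])
            lfc = np.where(shared | specific, model_lfc, 0.0)
        mu = mu0 * np.exp2(lfc) * sf[sid]
        p = nb_n / (nb_n + mu)
        cols[sid] = rng.negative_binomial(nb_n, p)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return CountMatrix(counts=counts, samples=samples, size_factors=sf)


# ---------------------------------------------------------------------------
# differential-expression result tables
# ---------------------------------------------------------------------------

def simulate_de_tables(
    truth: pd.DataFrame,
    power: float = 0.9,
    seed: int = 0,
    per_background: bool = False,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Parametric DESeq2-style result tables for 3 designs x 2 deletion models.

    Planted genes draw "significant" (padj < 0.05 after BH) independently per
    table with probability ``power``; null genes carry uniform p-values;
    log2FoldChange signs match the truth for planted genes. Background-
    specific genes are never significant in the cross-background design (that
    design encodes reproducibility across backgrounds, which they lack) but
    reach significance at ``power`` in the pooled designs.

    With ``per_background`` true, two extra tables per model (keys
    ``pairwise_H9`` / ``pairwise_CT2``) emulate the within-background pairwise
    analyses: background-specific genes are significant only in their own
    background's table.
    """
    if not (0.0 <= power <= 1.0):
        raise ValueError("power must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = truth.index.to_numpy()
    n = len(gene_ids)
    status = truth["status"].to_numpy()
    spec_bg = truth["specific_background"].to_numpy()
    base_mean = np.exp(rng.uniform(np.log(20), np.log(2000), size=n))

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    keys: list[tuple[str, str]] = [(m, d) for m in MODELS for d in DESIGNS]
    if per_background:
        keys += [(m, f"pairwise_{bg}") for m in MODELS for bg in BACKGROUNDS]
    for model, design in keys:
        true_lfc = truth[f"lfc_{model}"].to_numpy()
        planted = status != "null"
        eligible = planted.copy()
        is_specific = status == "background_specific"
        if design == "crossbg":
            eligible &= ~is_specific
        elif design.startswith("pairwise_"):
            bg = design.split("_", 1)[1]
            eligible &= ~is_specific | (spec_bg == bg)
        hit = eligible & (rng.random(n) < power)
        pvalue = rng.random(n)
        pvalue[hit] = rng.random(hit.sum()) * 1e-8
        lfc = rng.normal(0.0, 0.15, size=n)
        lfc[planted] = true_lfc[planted] + rng.normal(0.0, 0.1, size=planted.sum())
        padj = multipletests(pvalue, method="fdr_bh")[1]
        tables[(model, design)] = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "baseMean": base_mean,
                "log2FoldChange": lfc,
                "pvalue": pvalue,
                "padj": padj,
            }
        )
    return tables


def two_group_de_test(
    counts: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Welch t-test on log2 normalized counts, BH-adjusted.

    A sanity cross-check for simulated counts (does a planted effect show up
    at all?) — deliberately *not* an emulation of a negative-binomial GLM;
    real DE tables are expected to come from a dedicated DE tool.
    Normalization uses median-of-ratios size factors, which are robust to
    the composition bias a planted asymmetric effect induces in raw library
    sizes.
    """
    from scipy import stats as _stats

    mat = counts.counts
    logs = np.log(mat.where(mat > 0))
    ref = logs.mean(axis=1)  # log geometric mean over samples
    usable = np.isfinite(ref)
    sf = np.exp((logs[usable] - ref[usable].to_numpy()[:, None]).median(axis=0))
    norm = np.log2(mat / sf + 1.0)
    a = norm[list(group_a)].to_numpy()
    b = norm[list(group_b)].to_numpy()
    res = _stats.ttest_ind(a, b, axis=1, equal_var=False)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    pvalue = np.nan_to_num(res.pvalue, nan=1.0)
    return pd.DataFrame(
        {
            "gene_id": counts.counts.index,
            "baseMean": counts.counts.mean(axis=1).to_numpy(),
            "log2FoldChange": lfc,
            "pvalue": pvalue,
            "padj": multipletests(pvalue, method="fdr_bh")[1],
        }
    )


# ---------------------------------------------------------------------------
# window-score tables
# ---------------------------------------------------------------------------

def simulate_window_scores(
    registry: Sequence[SnoRNACopy],
    genes: Sequence[GeneModel],
    retained: Mapping[str, Sequence[TranscriptModel]],
    target_genes: Sequence[str],
    enrichment_fold: float = 2.5,
    background_event_rate: float = 2.0,
    background_windows_per_gene: float = 25.0,
    decoy_rate: float = 0.3,
    run_length_range: tuple[int, int] = (3, 6),
    p_group3: float = 0.8,
    p_ase2: float = 0.85,
    p_utr5: float = 0.7,
    score_threshold: float = 0.98,
    window_length: int = 13,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window-score table with planted >= 3-window runs of score >= threshold.

    Planted runs land on ``target_genes`` at ``enrichment_fold`` times the
    per-gene background event rate, biased (for target genes) toward
    group-III SNORD116 copies, the ASE2 snoRNA segment and the targets'
    5' UTR space. Sub-threshold scatter windows plus short (< 3 window)
    high-score decoys are added everywhere so the consecutive-window filter
    has something to reject; decoys never share a (copy, gene) pair with a
    planted run, so merged interactions equal planted runs exactly.

    Returns ``(windows, planted)``: the window table (canonical columns,
    ``window_length`` in attrs) and one row per planted run.
    """
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    rng = np.random.default_rng(seed)
    reg = list(registry)
    by_id = registry_index(reg)
    group3 = [c for c in reg if c.group == "III"]
    target_set = set(target_genes)
    gene_index = {g.gene_id: g for g in genes}
    for t in target_set:
        if t not in gene_index:
            raise ValueError(f"target gene {t} not in annotation")

    rows: list[tuple] = []
    planted_rows: list[dict] = []
    planted_pairs: set[tuple[str, str]] = set()

    lmin, lmax = run_length_range
    for gene in genes:
        on_target = gene.gene_id in target_set
        rate = background_event_rate * (enrichment_fold if on_target else 1.0)
        n_events = rng.poisson(rate)
        for _ in range(n_events):
            # one planted run per (copy, gene) pair, so merged interactions
            # correspond 1:1 to planted runs
            copy = None
            for _try in range(100):
                # the same copy-choice bias applies everywhere so the
                # group-III event rate on targets stays enrichment_fold x
                # the background group-III rate (the quantity the matched
                # control analysis measures)
                cand = (
                    group3[rng.integers(len(group3))]
                    if rng.random() < p_group3
                    else reg[rng.integers(len(reg))]
                )
                if (cand.copy_id, gene.gene_id) not in planted_pairs:
                    copy = cand
                    break
            if copy is None:  # pragma: no cover - all 78 copies taken
                continue
            n_win = int(rng.integers(lmin, lmax + 1))
            span_nt = window_length + n_win - 1
            sno_start = _draw_sno_start(copy, span_nt, p_ase2, rng)
            left = _draw_target_left(
                gene, retained.get(gene.gene_id, ()), span_nt,
                p_utr5 if on_target else 0.0, rng,
            )
            step = 1 if gene.strand == "+" else -1
            # first window of the run: leftmost for +, rightmost for -
            t_start = left if step == 1 else left + n_win - 1
            for k in range(n_win):
                rows.append(
                    (
                        copy.copy_id,
                        sno_start + k,
                        gene.gene_id,
                        gene.chrom,
                        t_start + step * k,
                        gene.strand,
                        score_threshold + rng.random() * (1.0 - score_threshold),
                    )
                )
            planted_pairs.add((copy.copy_id, gene.gene_id))
            planted_rows.append(
                {
                    "sno_id": copy.copy_id,
                    "gene_id": gene.gene_id,
                    "chrom": gene.chrom,
                    "strand": gene.strand,
                    "sno_start": sno_start,
                    "target_start": min(t_start, t_start + step * (n_win - 1)),
                    "n_windows": n_win,
                }
            )

        # sub-threshold scatter (cannot pass the score filter)
        span = gene.span
        n_bg = rng.poisson(background_windows_per_gene)
        for _ in range(n_bg):
            copy = reg[rng.integers(len(reg))]
            rows.append(
                (
                    copy.copy_id,
                    int(rng.integers(0, copy.length - window_length + 1)),
                    gene.gene_id,
                    gene.chrom,
                    int(rng.integers(span.start, span.end - window_length + 1)),
                    gene.strand,
                    rng.random() * score_threshold,
                )
            )
        # short high-score decoys (pass the score filter, fail the run filter)
        n_decoy = rng.poisson(decoy_rate)
        for _ in range(n_decoy):
            for _try in range(50):
                copy = reg[rng.integers(len(reg))]
                if (copy.copy_id, gene.gene_id) not in planted_pairs:
                    break
            else:  # pragma: no cover - essentially unreachable
                continue
            n_win = int(rng.integers(1, 3))
            s0 = int(rng.integers(0, copy.length - window_length - n_win + 2))
            t0 = int(rng.integers(span.start, span.end - window_length - n_win + 2))
            step = 1 if gene.strand == "+" else -1
            for k in range(n_win):
                rows.append(
                    (
                        copy.copy_id,
                        s0 + k,
                        gene.gene_id,
                        gene.chrom,
                        t0 + step * k,
                        gene.strand,
                        score_threshold + rng.random() * (1.0 - score_threshold),
                    )
                )

    windows = pd.DataFrame(
        rows,
        columns=[
            "sno_id", "sno_start", "target_gene_id", "target_chrom",
            "target_start", "strand", "score",
        ],
    )
    windows = windows.drop_duplicates(
        subset=["sno_id", "sno_start", "target_gene_id", "target_start"]
    ).reset_index(drop=True)
    windows.attrs["window_length"] = int(window_length)
    planted = pd.DataFrame(
        planted_rows,
        columns=[
            "sno_id", "gene_id", "chrom", "strand", "sno_start",
            "target_start", "n_windows",
        ],
    )
    return windows, planted


def _draw_sno_start(
    copy: SnoRNACopy, span_nt: int, p_ase2: float, rng: np.random.Generator
) -> int:
    a2s, a2e = copy.ase2
    if rng.random() < p_ase2 and a2e - a2s >= span_nt:
        return int(rng.integers(a2s, a2e - span_nt + 1))
    return int(rng.integers(0, copy.length - span_nt + 1))


def _draw_target_left(
    gene: GeneModel,
    retained: Sequence[TranscriptModel],
    span_nt: int,
    p_utr5: float,
    rng: np.random.Generator,
) -> int:
    """Left genomic edge of the run footprint (footprint width = span_nt)."""
    if rng.random() < p_utr5:
        utr5 = [sp for t in retained for sp in t.utr5 if sp[1] - sp[0] >= span_nt]
        if utr5:
            s, e = utr5[rng.integers(len(utr5))]
            return int(rng.integers(s, e - span_nt + 1))
    span = gene.span
    return int(rng.integers(span.start, span.end - span_nt + 1))
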