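# Methods

This note documents the statistical procedures snordpipe implements, the
synthetic data model used to exercise them, the numerical and design choices
made where more than one reading was defensible, and what the tests do and
do not demonstrate.

## Coordinate and annotation conventions

All internal coordinates are 0-based half-open; GTF input (1-based closed)
is converted on read and back on write. Transcript 5'/3' UTRs are derived as
exonic space minus CDS space, split by genomic side of the CDS and oriented
by strand (on `-`, the 5'UTR occupies the highest coordinates). The
transcript filter keeps transcripts with support level (TSL) 1-3 **and** the
`basic` tag; a missing or non-numeric TSL fails the filter, since only
levels 1-3 are ever named as kept. GTF attribute parsing keeps *all*
repeated `tag` values so `tag "basic"` is detected regardless of position.

## DEG consensus

Directional significance: a gene is up iff padj < 0.05 and log2FC > 0, down
iff padj < 0.05 and log2FC < 0; missing padj and log2FC exactly 0 are
excluded (directions are defined by strict inequalities). Consensus across
the three per-deletion designs (cross-background-reproducible pairwise,
`~ background + condition + background:condition`, `~ condition`) defaults
to sign-consistent intersection; an identifier-only mode is available since
intersecting by gene ID alone is also a defensible reading. Cross-model
sharing is concordant by default (up∩up ∪ down∩down), with an
any-direction mode; concordant ⊆ any-direction always. Foreign DE tables
are trusted as-is — no re-adjustment of p-values; the DE engine itself is
out of scope. Two low-count filters are exposed through one `min_mean`
parameter (mean ≥ 1/sample for neuron-neuron contrasts; 39 for an ESC-scale
contrast with ~39 samples).

## Overlap permutation test

"Shuffle the lists, take the same number of up genes from the top and down
genes from the bottom" is implemented literally: per replicate each side's
list is independently permuted, the first n_up entries labeled up and the
last n_down labeled down (guaranteeing disjointness), and the statistic is
|up_a∩up_b| + |down_a∩down_b|. Whether the shuffled list is the full
tested-gene universe or only the significant genes is not decidable from
the description; the default shuffles the universe (sampling n_up + n_down
items requires a superset), with `shuffle_universe=False` exposing the
other reading. p = #(null ≥ observed)/n_perm with ties counted; a zero count
is reported as the upper bound 1/n_perm and flagged (`p_is_floor`).
Fold = observed/median(null); a zero median yields `inf`, never a crash.
For a common universe of size N the null up-overlap mean is
n_up_a·n_up_b/N, which the tests verify to 3 SE; with ~350 up + 350 down
significant genes in a 4000-gene universe the discrete null is smooth
enough that p-values are uniform to a Kolmogorov-Smirnov test over 500
simulated null datasets.

## Interaction filter

A window is (snoRNA copy, snoRNA offset, target gene, genomic position,
strand, score). "Consecutive" requires step-1 advancement on **both** the
snoRNA and the target simultaneously — a sliding duplex — with the target
advancing rightward on `+` targets and leftward on `-` targets; target-only
adjacency would merge unrelated duplexes. A maximal run of ≥ 3 windows all
scoring ≥ 0.98 yields exactly one event (a 5-window run is one event, not
three); duplicate coordinates are deduplicated, conflicting duplicate
scores are an error. Gap tolerance defaults to 0 with a `max_gap` escape
hatch, since whether snoGloBe's merge option bridges missing windows is
not documented. The window length is a per-table parameter (default 13 nt, a
snoGloBe-like width; output-table dialects vary, so the reader takes a
column map with a documented default).
Per-group event means divide by the full group size including zero-count
copies.

## Matched-control enrichment

Covariates: exonic length = bp of the union of exons over retained
transcripts; GC over that same space; expression = mean library-size
normalized count (log2(x+1) before testing by default — the rank test is
transform-invariant, the report shows the tested scale). "The Wilcoxon
test" is taken as the two-sample rank-sum (Mann-Whitney) test, two-sided
with tie correction, applied marginally to the three covariates; α = 0.05
(a conventional default, configurable). Control lists are drawn by
rejection sampling from the universe minus the query, may overlap one
another, and must pass all three tests. Enrichment of S ∈ {mean, median,
sum} uses fold = S(query)/median over control-list values (median for
consistency with the overlap test's convention; `fold_ref="mean"`
available) and the same floored permutation p. The median statistic is
coarse for small per-gene counts (control-list medians are small integers),
so fold-recovery checks use the sum/mean statistics.

## Positional analysis

snoRNA side: event center = floored midpoint of the merged snoRNA
interval; relative position = center/copy length, histogrammed at 0.01
width with per-group mean box positions overlaid. Target side: the feature
space is the union of retained-transcript exons, plus per-transcript
introns minus exonic bp; exonic bp are labeled 5'UTR/CDS/3'UTR by majority
vote of the covering retained transcripts (ties → CDS; bp covered only by
non-coding transcripts → "other") — a deterministic rule for bp whose
label differs between transcripts. Events are classified per gene over the union space:
exon-only / intron-only / both = junction; exonic events are sub-labeled by
the set of subspaces overlapped (5'UTR+CDS and 3'UTR+CDS straddles kept
separate, anything else "other"). The background basis reports bp
fractions of the same space. Events outside the space go to an explicit
unassigned bucket. Metagene mapping: [0,1) 5'UTR, [1,2) gene body (CDS for
coding transcripts; whole exonic span for non-coding), [2,3) 3'UTR; an
event midpoint is mapped per retained transcript with its unit weight split
over the transcripts that map it (a `--longest-transcript`-style single
representative is a trivial restriction of the mapping). Densities
normalize to integrate to 1. Midpoints and offsets are computed in
continuous coordinates so that mirroring an annotation to the opposite
strand leaves every profile unchanged (verified by test).

## Synthetic data model

The generator reproduces the statistical structure the analysis assumes —
not sequencing reads, isoform usage, or batch structure beyond
background-specific effects.

- **Annotation**: genes with 1-3 transcripts and 1-8 exons (80-400 bp exons,
  40-300 bp introns); each gene's first transcript has TSL 1-3 + basic so
  every gene survives the standard filter, other transcripts draw mixed TSL
  1-5/missing and basic flags; coding transcripts get a CDS strictly inside
  exon space so both UTRs are non-empty. Sequences realize the target GC
  exactly by construction.
- **snoRNA registry**: 30 SNORD116 copies (groups I/II/III of 9/15/6 by copy
  index) and 48 SNORD115 copies. Copy lengths and box coordinates are not
  inputs this package ships; lengths draw from 90-100 nt and boxes sit at canonical
  relative positions, leaving ≥ 15 nt between C' and D — ASE2 is modeled as
  exactly that segment.
- **Counts**: NB with variance μ + αμ² (α = 0.05), per-gene μ log-uniform on
  [20, 2000], 6 replicates per background × genotype cell, size factors
  uniform on [0.7, 1.3]. Shared DEGs are perturbed (default |log2FC| = 1) in
  both backgrounds and both deletions; background-specific DEGs in exactly
  one background.
- **DE tables** are parametric draws from the truth (the internal two-group
  count test is a cross-check only and is *not* a DESeq2 emulation):
  eligible planted genes draw p ~ U(0, 1e-8) with probability `power`,
  independently per design and model; everything else draws uniform p;
  padj is BH within each table, so tables exhibit realistic BH false
  positives. Background-specific genes are never eligible in the
  cross-background design (that design encodes cross-background
  reproducibility, which they lack) but are eligible in the pooled designs
  and in their own background's pairwise table. This yields shared-set
  recall ≈ power⁶ (3 designs × 2 models) and excludes background-specific
  genes from the shared set structurally rather than by luck.
- **Window scores**: per gene, Poisson-many planted runs (rate 2.0/gene for
  background genes, ×2.5 on targets), run lengths 3-6 windows at step 1,
  scores U[0.98, 1); the group-III copy-choice bias (0.8) applies to *all*
  genes so the group-III event rate on targets stays exactly
  `enrichment_fold` × the background group-III rate — the quantity the
  matched-control analysis measures. ASE2 placement bias 0.85 everywhere;
  5'UTR placement bias 0.7 on targets. Sub-threshold scatter (~25
  windows/gene, scores < 0.98) and short high-score decoys (1-2 windows)
  exercise both filter conditions; planted runs never share a (copy, gene)
  pair with each other or with decoys, so merged events correspond 1:1 to
  planted runs.

All generators are seed-deterministic; the pipeline derives stage seeds
from one root seed via `SeedSequence.spawn`.

## Problem sizes

Defaults were sized so a desk-scale run exercises every stage with
realistic proportions: 800 genes (42 planted shared, 50 background-
specific), 10 000 permutations, 100 matched lists of 42. The test suite
uses 250-2000 genes, 200-500 simulation replicates for calibration and
recovery checks, 400-2000 permutation replicates, and 1000 random vectors
for the merge oracle; a full default pipeline run takes a few seconds on
one core.

## Known limitations

- DE tables are parametric; power is exactly per-design-independent by
  construction, which real DESeq2 designs sharing samples would violate.
  Recovery results therefore validate the *consensus logic*, not DESeq2
  behavior on correlated designs.
- The matched-control fold is mildly attenuated in full pipeline runs
  because planted target genes that the consensus fails to recover remain
  in the control universe with elevated event rates; the module-level
  recovery check (query = all planted targets) recovers the planted fold
  within [2.0, 3.0].
- The generator does not simulate splicing isoform usage, FASTQ-level
  noise, or batch effects beyond background-specific DEGs; passing tests
  say nothing about read-level artifacts.
- The snoRNA registry's lengths and box coordinates are synthetic
  placeholders; analyses that depend on absolute (not relative) box
  positions should supply a real registry.
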