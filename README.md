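# snordpipe

Consensus differential-expression calling and orphan C/D-box snoRNA
target-enrichment analysis for isogenic Prader-Willi syndrome (PWS) models.

## The problem

PWS is caused by loss of paternal expression at chr15q11-q13, and atypical
microdeletions point at the tandem cluster of 30 **SNORD116** C/D-box
snoRNAs as the likely driver. SNORD116 copies (groups I/II/III = copies
1-9/10-24/25-30) are *orphans*: they have no rRNA complementarity and no
established targets. A rigorous way to look for their targets is to engineer
two deletions (the whole SNHG14 unit, `lgDEL`, and the SNORD116 cluster
alone, `smDEL`) in **two** genetic backgrounds, call differential expression
against each isogenic control, keep only genes dysregulated consistently
across designs, backgrounds and deletions, and then ask whether that gene
set is enriched for *predicted* SNORD116 binding.

`snordpipe` implements the downstream statistics of that analysis as a
tested, reusable library plus CLI:

- **DEG consensus** — padj < 0.05 with directional (log2FC sign) splitting,
  intersection across three statistical designs per deletion model, and
  concordant intersection across the two models
  (`snordpipe.consensus`).
- **Directional overlap permutation test** — each side's tested-gene list is
  shuffled; the first *n*\_up entries are labeled up and the last *n*\_down
  down; the replicate statistic is |up∩up| + |down∩down|. Enrichment is
  observed / median(null); *p* = #(null ≥ observed)/*n*\_perm, reported as
  the upper bound 1/*n*\_perm when the count is zero
  (`snordpipe.permutation`).
- **Consecutive-window interaction filter** — snoGloBe-style window scores
  are merged into predicted targeting events: at least *w* = 3 consecutive
  windows (step 1 nt on both the snoRNA and, strand-appropriately, the
  target) with score ≥ *t* = 0.98; a maximal qualifying run is one event
  (`snordpipe.interactions`).
- **Covariate-matched control enrichment** — control gene lists matched to
  the query on exonic length, GC content and mean normalized expression
  (two-sided Wilcoxon rank-sum, all three *p* > α) by rejection sampling;
  fold and permutation-style *p* for the mean/median/sum of per-gene event
  counts (`snordpipe.matching`).
- **Positional profiles** — event-center positions along the snoRNA relative
  to the C/D'/C'/D boxes (group III events should sit in ASE2, the guide
  segment upstream of the D box); feature coverage over
  exon/intron/junction and 5'UTR/CDS/3'UTR space (TSL 1-3, `basic`-tag
  transcripts only); and a metagene density with [0,1) = 5'UTR,
  [1,2) = gene body, [2,3) = 3'UTR (`snordpipe.positional`).
- **Over-representation** — hypergeometric upper-tail *p*, BH adjustment,
  and foldEnrichment = GeneRatio/BgRatio for arbitrary GMT collections
  (`snordpipe.enrichment`).
- **Synthetic data** — every input the pipeline consumes (GTF + FASTA
  annotation, negative-binomial counts for the 2-background × 3-genotype
  design, DE result tables with controlled per-design power, window-score
  tables with planted high-score runs) is generated with known ground truth
  (`snordpipe.synthetic`), so recovery is measurable end to end.

## Worked example

```python
from snordpipe.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(
    out_dir="demo", seed=7, n_genes=400, n_perm=2000, k_control_lists=50,
))
st = summary["stages"]
print("shared genes:", st["consensus"]["n_shared"])
print("smDEL overlap:", st["overlap_permutation"]["smDEL"])
print("targeting sum:", st["matched_enrichment"]["enrichment"]["sum"])
```

prints

```
shared genes: 20
smDEL overlap: {'observed': 32, 'null_median': 5.0, 'fold': 6.4, 'p_value': 0.0005, 'p_is_floor': True}
targeting sum: {'observed': 66.0, 'fold': 2.0625, 'p_value': 0.02, 'p_is_floor': True}
```

Read: 20 of the 42 planted consistently dysregulated genes survive the full
six-way consensus at per-design power 0.9 (expected recall 0.9⁶ ≈ 0.53); the
smDEL cross-background DEG overlap (32 genes) is 6.4× its shuffled-null
median with *p* reported as the 1/2000 bound; and the planted ~2.5-fold
group-III targeting enrichment is recovered as a 2.06-fold excess of
targeting-event counts over 50 covariate-matched control lists. `demo/`
contains the per-stage TSVs, BED tracks and `summary.json`.

The same stages are exposed on the command line:

```bash
snordpipe run --seed 7 --out demo
snordpipe sno-filter --windows demo/window_scores.tsv --t 0.98 --w 3
snordpipe overlap-perm --a up.txt,down.txt --b up2.txt,down2.txt \
    --universe-a genes_a.txt --universe-b genes_b.txt --n-perm 10000 --seed 1
```

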