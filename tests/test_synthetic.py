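"""Generator invariants: registry structure, GC control, NB count effects,
DE-table power/FDR structure, window planting, and seed determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snordpipe.genome import filter_transcripts
from snordpipe.intervals import merge
from snordpipe.interactions import FilterParams, merge_consecutive_windows
from snordpipe.snorna import build_snorna_registry
from snordpipe.synthetic import (
    build_toy_annotation,
    make_truth_table,
    simulate_counts,
    simulate_de_tables,
    simulate_window_scores,
)


# ------------------------------------------------------------------ registry

def test_registry_copy_numbers_and_groups(registry):
    n116 = [c for c in registry if c.cluster == "SNORD116"]
    n115 = [c for c in registry if c.cluster == "SNORD115"]
    assert len(n116) == 30
    assert len(n115) == 48
    sizes = pd.Series([c.group for c in n116]).value_counts().to_dict()
    assert sizes == {"I": 9, "II": 15, "III": 6}
    assert all(c.group is None for c in n115)


def test_registry_box_order_and_bounds(registry):
    for c in registry:
        boxes = [c.box_c, c.box_dprime, c.box_cprime, c.box_d]
        flat = [x for b in boxes for x in b]
        assert flat == sorted(flat), c.copy_id  # C < D' < C' < D, 5'->3'
        assert 0 <= flat[0] and flat[-1] <= c.length
        a2s, a2e = c.ase2
        assert a2e - a2s >= 15  # guide segment long enough for a window run


# --------------------------------------------------------------- annotation

def test_annotation_partition_and_gc():
    genes, seqs = build_toy_annotation(30, gc_targets=0.60, seed=9)
    assert len(genes) == 30
    for g in genes:
        seq = seqs[g.gene_id]
        assert len(seq) == g.span.width
        gc = sum(seq.count(b) for b in "GC") / len(seq)
        assert abs(gc - 0.60) <= 0.05
        for t in g.transcripts:
            if t.is_coding:
                tiled = merge(list(t.utr5) + list(t.cds) + list(t.utr3))
                assert tiled == list(t.exons)
                assert t.utr5 and t.utr3  # CDS strictly inside exon space


def test_annotation_seed_determinism(tmp_path):
    from snordpipe.io import write_gtf

    for i, out in enumerate(["a.gtf", "b.gtf"]):
        genes, _ = build_toy_annotation(15, seed=77)
        write_gtf(genes, tmp_path / out)
    assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()


def test_annotation_rejects_bad_gc():
    with pytest.raises(ValueError):
        build_toy_annotation(5, gc_targets=1.5)
    with pytest.raises(ValueError):
        build_toy_annotation(0)


# -------------------------------------------------------------------- counts

def test_counts_planted_fold_change_recovery():
    """Planted log2FC of 1 doubles the deletion-sample group mean."""
    n = 600
    gene_ids = [f"G{i}" for i in range(n)]
    truth = make_truth_table(
        gene_ids, n_shared_up=500, n_shared_down=0, n_background_specific=0, seed=1
    )
    cm = simulate_counts(
        gene_ids, truth, n_reps=6, dispersion=0.05,
        size_factor_range=(1.0, 1.0), seed=2,
    )
    meta = cm.samples
    wt = meta.index[meta["genotype"] == "WT"]
    dele = meta.index[meta["genotype"] != "WT"]
    planted = truth.index[truth["status"] == "shared_up"]
    ratio = cm.counts.loc[planted, dele].mean(axis=1) / cm.counts.loc[
        planted, wt
    ].mean(axis=1)
    # sampling noise at n_reps=6, alpha=0.05 leaves per-gene ratios fairly
    # wide; the central tendency must sit at 2
    assert 1.95 <= ratio.median() <= 2.05
    assert (ratio.between(1.7, 2.3)).mean() >= 0.80
    null = truth.index[truth["status"] == "null"]
    null_ratio = cm.counts.loc[null, dele].mean(axis=1) / cm.counts.loc[
        null, wt
    ].mean(axis=1)
    assert 0.95 <= null_ratio.median() <= 1.05


def test_counts_validation():
    gene_ids = ["G1", "G2"]
    truth = make_truth_table(gene_ids, 0, 0, 0)
    with pytest.raises(ValueError):
        simulate_counts(gene_ids, truth, n_reps=1)
    with pytest.raises(ValueError):
        simulate_counts(gene_ids, truth, dispersion=0.0)
    with pytest.raises(ValueError):
        make_truth_table(["G1"], n_shared_up=2, n_shared_down=0, n_background_specific=0)


def test_background_specific_only_perturbs_one_background():
    gene_ids = [f"G{i}" for i in range(200)]
    truth = make_truth_table(
        gene_ids, n_shared_up=0, n_shared_down=0, n_background_specific=100, seed=3
    )
    cm = simulate_counts(
        gene_ids, truth, n_reps=8, size_factor_range=(1.0, 1.0), seed=4
    )
    meta = cm.samples
    spec = truth[truth["status"] == "background_specific"]
    for bg in ("H9", "CT2"):
        other = "CT2" if bg == "H9" else "H9"
        genes_bg = spec.index[spec["specific_background"] == bg]
        wt_o = meta.index[(meta["background"] == other) & (meta["genotype"] == "WT")]
        del_o = meta.index[(meta["background"] == other) & (meta["genotype"] != "WT")]
        ratio = cm.counts.loc[genes_bg, del_o].mean(axis=1) / cm.counts.loc[
            genes_bg, wt_o
        ].mean(axis=1)
        assert 0.9 <= ratio.median() <= 1.1  # untouched in the other background


def test_two_group_cross_check_detects_planted_effects():
    """The simple log-scale t-test cross-check sees planted fold changes."""
    from snordpipe.synthetic import two_group_de_test

    gene_ids = [f"G{i}" for i in range(300)]
    truth = make_truth_table(gene_ids, 50, 0, 0, effect_size=2.0, seed=60)
    cm = simulate_counts(gene_ids, truth, n_reps=6, seed=61)
    meta = cm.samples
    res = two_group_de_test(
        cm,
        meta.index[meta["genotype"] != "WT"],
        meta.index[meta["genotype"] == "WT"],
    ).set_index("gene_id")
    planted = truth.index[truth["status"] == "shared_up"]
    null = truth.index[truth["status"] == "null"]
    assert (res.loc[planted, "padj"] < 0.05).mean() > 0.9
    # a crude t-test cross-check is not a calibrated DE engine; nulls stay
    # mostly non-significant but carry some residual composition bias
    assert (res.loc[null, "padj"] < 0.05).mean() < 0.2
    assert (res.loc[planted, "log2FoldChange"] > 0).all()


# ----------------------------------------------------------------- DE tables

def test_de_tables_power_extremes():
    gene_ids = [f"G{i}" for i in range(400)]
    truth = make_truth_table(gene_ids, 30, 30, 40, seed=5)
    tables = simulate_de_tables(truth, power=1.0, seed=6, per_background=True)
    shared = truth.index[truth["status"].isin(["shared_up", "shared_down"])]
    specific = truth[truth["status"] == "background_specific"]
    # the generator's contract is on raw p-values: at power 1 every eligible
    # planted gene draws a near-zero p; ineligible genes draw uniform p (so
    # they may occasionally reach padj < 0.05 through BH, as in real tables)
    for (model, design), tbl in tables.items():
        tbl = tbl.set_index("gene_id")
        assert (tbl.loc[shared, "pvalue"] < 1e-6).all()
        assert (tbl.loc[shared, "padj"] < 0.05).all()
        # signs match the truth for planted genes
        assert (
            np.sign(tbl.loc[shared, "log2FoldChange"])
            == np.sign(truth.loc[shared, f"lfc_{model}"])
        ).all()
        if design == "crossbg":
            assert not (tbl.loc[specific.index, "pvalue"] < 1e-6).any()
        elif design.startswith("pairwise_"):
            bg = design.split("_", 1)[1]
            own = specific.index[specific["specific_background"] == bg]
            other = specific.index[specific["specific_background"] != bg]
            assert (tbl.loc[own, "pvalue"] < 1e-6).all()
            assert not (tbl.loc[other, "pvalue"] < 1e-6).any()
        else:
            assert (tbl.loc[specific.index, "pvalue"] < 1e-6).all()


def test_de_tables_power_zero_planted_look_null():
    gene_ids = [f"G{i}" for i in range(2000)]
    truth = make_truth_table(gene_ids, 100, 100, 0, seed=7)
    tables = simulate_de_tables(truth, power=0.0, seed=8)
    planted = truth.index[truth["status"] != "null"]
    tbl = tables[("smDEL", "condition")].set_index("gene_id")
    ks = stats.kstest(tbl.loc[planted, "pvalue"], "uniform")
    assert ks.pvalue > 0.01


def test_de_tables_null_false_positive_control():
    gene_ids = [f"G{i}" for i in range(10_000)]
    truth = make_truth_table(gene_ids, 0, 0, 0)
    tbl = simulate_de_tables(truth, power=0.5, seed=9)[("smDEL", "condition")]
    fp = (tbl["padj"] < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / len(tbl))
    assert fp <= 0.05 + 3 * se


# ------------------------------------------------------------- window scores

def _windows_setup(seed=21, **kwargs):
    genes, _ = build_toy_annotation(40, seed=seed)
    retained, _ = filter_transcripts(genes)
    registry = build_snorna_registry(seed=seed)
    targets = [g.gene_id for g in genes[:10]]
    return genes, retained, registry, targets


def test_windows_no_events_merge_to_nothing():
    genes, retained, registry, targets = _windows_setup()
    windows, planted = simulate_window_scores(
        registry, genes, retained, targets,
        background_event_rate=0.0, enrichment_fold=1.0, decoy_rate=0.0, seed=1,
    )
    assert len(planted) == 0
    assert (windows["score"] < 0.98).all()
    assert merge_consecutive_windows(windows, FilterParams()) == []
    # with short high-score decoys present the run filter still rejects all
    windows2, _ = simulate_window_scores(
        registry, genes, retained, targets,
        background_event_rate=0.0, enrichment_fold=1.0, decoy_rate=2.0, seed=1,
    )
    assert (windows2["score"] >= 0.98).any()
    assert merge_consecutive_windows(windows2, FilterParams()) == []


def test_windows_planted_runs_merge_one_to_one():
    genes, retained, registry, targets = _windows_setup()
    windows, planted = simulate_window_scores(
        registry, genes, retained, targets,
        background_event_rate=1.5, enrichment_fold=2.0,
        run_length_range=(3, 3), seed=2,
    )
    merged = merge_consecutive_windows(windows, FilterParams())
    assert len(merged) == len(planted)
    got = {
        (x.sno_id, x.target_gene_id, x.sno_start, x.target.start)
        for x in merged
    }
    want = {
        (r.sno_id, r.gene_id, r.sno_start, r.target_start)
        for r in planted.itertuples()
    }
    assert got == want
    assert all(x.n_windows == 3 for x in merged)


def test_windows_seed_determinism_and_fold_validation():
    genes, retained, registry, targets = _windows_setup()
    w1, p1 = simulate_window_scores(registry, genes, retained, targets, seed=5)
    w2, p2 = simulate_window_scores(registry, genes, retained, targets, seed=5)
    pd.testing.assert_frame_equal(w1, w2)
    pd.testing.assert_frame_equal(p1, p2)
    with pytest.raises(ValueError):
        simulate_window_scores(registry, genes, retained, targets, enrichment_fold=0.5)
    with pytest.raises(ValueError):
        simulate_window_scores(registry, genes, retained, ["NOPE"])
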