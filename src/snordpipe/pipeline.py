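"""End-to-end orchestration of the synthetic PWS snoRNA-target analysis.

Stages: synthetic input generation -> low-count filter -> per-model
three-design DEG consensus -> cross-model shared gene set -> cross-background
directional overlap permutation tests -> consecutive-window interaction
filter -> covariate-matched targeting enrichment -> positional profiles ->
optional gene-set over-representation. Each stage writes a TSV; the run ends
with a machine-readable JSON summary embedding the config and input hashes.
Fully deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import consensus as cns
from . import io as sio
from .interactions import FilterParams, count_events, merge_consecutive_windows
from .matching import compute_covariates, enrichment_vs_controls, sample_matched_lists
from .enrichment import gene_set_enrichment
from .genome import filter_transcripts
from .permutation import overlap_permutation_test
from .positional import (
    background_profile,
    build_feature_space,
    classify_intervals,
    metagene_density,
    sno_relative_positions,
)
from .report import RunSummary
from .snorna import build_snorna_registry
from .synthetic import (
    BACKGROUNDS,
    DESIGNS,
    MODELS,
    build_toy_annotation,
    make_truth_table,
    simulate_counts,
    simulate_de_tables,
    simulate_window_scores,
)

log = logging.getLogger("snordpipe")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """All pipeline thresholds, sizes and seeds (serializable)."""

    out_dir: str = "snordpipe_run"
    seed: int = 0
    # synthetic sizes
    n_genes: int = 800
    n_chroms: int = 2
    n_reps: int = 6
    n_shared_up: int = 21
    n_shared_down: int = 21
    n_background_specific: int = 50
    de_power: float = 0.9
    enrichment_fold: float = 2.5
    background_event_rate: float = 2.0
    # analysis thresholds
    padj_lt: float = 0.05
    min_mean: float = 1.0
    score_threshold: float = 0.98
    min_run: int = 3
    n_perm: int = 10_000
    k_control_lists: int = 100
    alpha_match: float = 0.05
    # optional external inputs
    gmt_path: Optional[str] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic analysis; returns (and writes) the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root_seed.spawn(8)]
    summary: dict = {"config": config.to_dict(), "stages": {}, "input_hashes": {}}
    log.info("run seed %d -> stage seeds %s", config.seed, seeds)
    t_stage = time.perf_counter()

    def _tick(stage_name: str) -> float:
        nonlocal t_stage
        elapsed, t_stage = time.perf_counter() - t_stage, time.perf_counter()
        return elapsed

    # --- stage: synthetic inputs -----------------------------------------
    stage = "synthetic"
    try:
        genes, sequences = build_toy_annotation(
            config.n_genes, n_chroms=config.n_chroms, seed=seeds[0]
        )
        gene_ids = [g.gene_id for g in genes]
        truth = make_truth_table(
            gene_ids,
            n_shared_up=config.n_shared_up,
            n_shared_down=config.n_shared_down,
            n_background_specific=config.n_background_specific,
            seed=seeds[1],
        )
        counts = simulate_counts(gene_ids, truth, n_reps=config.n_reps, seed=seeds[2])
        tables = simulate_de_tables(
            truth, power=config.de_power, seed=seeds[3], per_background=True
        )
        retained, _ = filter_transcripts(genes)
        registry = build_snorna_registry(seed=seeds[4])
        planted_targets = sorted(
            truth.index[truth["status"].isin(["shared_up", "shared_down"])]
        )
        truth.loc[planted_targets, "is_planted_target"] = True
        windows, planted_runs = simulate_window_scores(
            registry,
            genes,
            retained,
            planted_targets,
            enrichment_fold=config.enrichment_fold,
            background_event_rate=config.background_event_rate,
            score_threshold=config.score_threshold,
            seed=seeds[5],
        )
        sio.write_gtf(genes, out / "annotation.gtf")
        sio.write_fasta(sequences, out / "genes.fasta")
        counts.counts.to_csv(out / "counts.tsv", sep="\t")
        counts.samples.to_csv(out / "samples.tsv", sep="\t")
        truth.to_csv(out / "truth.tsv", sep="\t")
        sio.write_window_scores(windows, out / "window_scores.tsv")
        for (model, design), tbl in tables.items():
            sio.write_de_table(tbl, out / f"de_{model}_{design}.tsv")
        for name in ("annotation.gtf", "counts.tsv", "window_scores.tsv"):
            summary["input_hashes"][name] = _sha256(out / name)
        summary["stages"][stage] = {
            "n_genes": len(genes),
            "n_planted_shared": len(planted_targets),
            "n_planted_runs": int(len(planted_runs)),
            "n_windows": int(len(windows)),
        }
        log.info("%s (%.2fs): %d genes, %d windows", stage, _tick(stage), len(genes), len(windows))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: low-count filter + consensus ------------------------------
    stage = "consensus"
    try:
        kept = cns.filter_low_counts(counts, config.min_mean)
        model_sets = {}
        for model in MODELS:
            degsets = [
                cns.significant_degs(
                    tables[(model, d)], f"{model}:{d}", config.padj_lt
                )
                for d in DESIGNS
            ]
            model_sets[model] = cns.consensus_across_designs(
                degsets, contrast_id=f"{model}:consensus"
            )
        shared = cns.shared_across_models(
            model_sets["smDEL"], model_sets["lgDEL"], mode="concordant"
        )
        shared_sorted = sorted(shared)
        pd.Series(shared_sorted, name="gene_id").to_csv(
            out / "shared_genes.tsv", sep="\t", index=False
        )
        truth_shared = set(planted_targets)
        recall = (
            len(shared & truth_shared) / len(truth_shared) if truth_shared else 0.0
        )
        false_shared = sorted(shared - truth_shared)
        summary["stages"][stage] = {
            "n_low_count_kept": len(kept),
            "n_consensus_smDEL": len(model_sets["smDEL"].all_degs),
            "n_consensus_lgDEL": len(model_sets["lgDEL"].all_degs),
            "n_shared": len(shared),
            "planted_shared_recall": recall,
            "n_unplanted_in_shared": len(false_shared),
        }
        log.info("%s (%.2fs): %d shared genes (recall %.3f)", stage, _tick(stage), len(shared), recall)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: cross-background overlap permutation ----------------------
    stage = "overlap_permutation"
    try:
        perm_results = {}
        for i, model in enumerate(MODELS):
            a = cns.significant_degs(
                tables[(model, f"pairwise_{BACKGROUNDS[0]}")],
                f"{model}:{BACKGROUNDS[0]}",
                config.padj_lt,
            )
            b = cns.significant_degs(
                tables[(model, f"pairwise_{BACKGROUNDS[1]}")],
                f"{model}:{BACKGROUNDS[1]}",
                config.padj_lt,
            )
            res = overlap_permutation_test(
                a, b, n_perm=config.n_perm, seed=seeds[6] + i
            )
            perm_results[model] = {
                "observed": res.observed,
                "null_median": res.null_median,
                "fold": res.fold,
                "p_value": res.p_value,
                "p_is_floor": res.p_is_floor,
            }
            np.savetxt(
                out / f"perm_null_{model}.tsv",
                res.null_values,
                fmt="%d",
                header="null_overlap",
                comments="",
            )
        summary["stages"][stage] = perm_results
        log.info("%s (%.2fs): %s", stage, _tick(stage), perm_results)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: interaction filter ----------------------------------------
    stage = "interaction_filter"
    try:
        params = FilterParams(
            score_threshold=config.score_threshold, min_run=config.min_run
        )
        interactions = merge_consecutive_windows(windows, params)
        per_copy, per_group_total, per_group_mean = count_events(
            interactions, registry
        )
        counts_df = per_copy.rename("n_events").to_frame()
        counts_df.to_csv(out / "event_counts_per_copy.tsv", sep="\t")
        sio.write_bed(
            [
                (x.target, f"{x.sno_id}|{x.target_gene_id}", x.mean_score * 1000)
                for x in interactions
            ],
            out / "events.bed",
        )
        summary["stages"][stage] = {
            "n_interactions": len(interactions),
            "per_group_total": {k: int(v) for k, v in per_group_total.items()},
            "per_group_mean": {k: float(v) for k, v in per_group_mean.items()},
        }
        log.info("%s (%.2fs): %d merged interactions", stage, _tick(stage), len(interactions))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: matched enrichment ----------------------------------------
    stage = "matched_enrichment"
    try:
        covariates = compute_covariates(genes, sequences, counts, retained)
        query = [g for g in shared_sorted if g in covariates.index]
        group_by_copy = {c.copy_id: c.group for c in registry}
        g3_events = [x for x in interactions if group_by_copy[x.sno_id] == "III"]
        per_gene = pd.Series(0, index=covariates.index, dtype=int)
        for x in g3_events:
            if x.target_gene_id in per_gene.index:
                per_gene[x.target_gene_id] += 1
        matched = sample_matched_lists(
            query,
            covariates,
            k=config.k_control_lists,
            alpha=config.alpha_match,
            seed=seeds[7],
        )
        enr = enrichment_vs_controls(
            per_gene.reindex(query).fillna(0), matched, per_gene
        )
        enr.to_csv(out / "targeting_enrichment.tsv", sep="\t")
        predicted_targets = {x.target_gene_id for x in interactions} & set(query)
        summary["stages"][stage] = {
            "n_query": len(query),
            "n_control_lists": len(matched.lists),
            "matching_attempts": matched.n_attempts,
            "n_query_predicted_targets": len(predicted_targets),
            "enrichment": {
                s: {
                    "observed": float(enr.loc[s, "observed"]),
                    "fold": float(enr.loc[s, "fold"]),
                    "p_value": float(enr.loc[s, "p_value"]),
                    "p_is_floor": bool(enr.loc[s, "p_is_floor"]),
                }
                for s in enr.index
            },
        }
        log.info("%s (%.2fs): fold(sum)=%.2f", stage, _tick(stage), enr.loc["sum", "fold"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: positional profiles ----------------------------------------
    stage = "positional"
    try:
        group_of = {c.copy_id: (c.group or c.cluster) for c in registry}
        shared_retained = {g: retained[g] for g in query if g in retained}
        spaces = build_feature_space(shared_retained)
        bg_prof = background_profile(spaces)
        ev_on_shared = [
            (x.target, x.target_gene_id)
            for x in g3_events
            if x.target_gene_id in spaces
        ]
        ev_prof, unassigned = classify_intervals(ev_on_shared, spaces)
        sio.write_bed(
            [(iv, gid, 0) for iv, gid in unassigned], out / "unassigned_events.bed"
        )
        meta = metagene_density(
            [
                (x.target, x.target_gene_id, group_of[x.sno_id])
                for x in interactions
                if x.target_gene_id in shared_retained
            ],
            shared_retained,
        )
        profiles = sno_relative_positions(interactions, registry)
        pos_rows = []
        for grp, prof in sorted(profiles.items()):
            for p in prof.positions:
                pos_rows.append({"group": grp, "relative_position": p})
        _write_tsv(pd.DataFrame(pos_rows), out / "sno_positions.tsv")
        summary["stages"][stage] = {
            "background_tier1": bg_prof.tier1,
            "background_tier2": bg_prof.tier2,
            "events_tier1": ev_prof.tier1,
            "events_tier2": ev_prof.tier2,
            "n_unassigned_events": ev_prof.n_unassigned,
            "metagene_weight": meta.weights,
        }
        log.info("%s (%.2fs): events 5'UTR fraction %.3f", stage, _tick(stage), ev_prof.tier2["utr5"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stage: gene-set over-representation (optional) --------------------
    stage = "gene_set_enrichment"
    try:
        if config.gmt_path:
            collections = sio.read_gmt(config.gmt_path)
            universe = list(truth.index)
            records = gene_set_enrichment(
                [g for g in shared_sorted if g in set(universe)],
                collections,
                universe,
            )
            _write_tsv(records, out / "gene_set_enrichment.tsv")
            summary["stages"][stage] = {
                "n_sets": len(records),
                "n_significant": int((records["padj"] < 0.05).sum()),
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {exc}") from exc

    RunSummary.model_validate(summary)  # schema check before writing
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
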