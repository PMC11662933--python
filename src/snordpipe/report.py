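"""Schema for the machine-readable run summary.

The pipeline validates its summary against these models before writing
``summary.json``, so downstream consumers can rely on the structure; every
number in the summary is recomputable from the per-stage TSVs next to it.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticStage(_Strict):
    n_genes: int
    n_planted_shared: int
    n_planted_runs: int
    n_windows: int


class ConsensusStage(_Strict):
    n_low_count_kept: int
    n_consensus_smDEL: int
    n_consensus_lgDEL: int
    n_shared: int
    planted_shared_recall: float
    n_unplanted_in_shared: int


class PermutationResult(_Strict):
    observed: int
    null_median: float
    fold: float
    p_value: float
    p_is_floor: bool


class InteractionStage(_Strict):
    n_interactions: int
    per_group_total: dict[str, int]
    per_group_mean: dict[str, float]


class EnrichmentStat(_Strict):
    observed: float
    fold: float
    p_value: float
    p_is_floor: bool


class MatchedEnrichmentStage(_Strict):
    n_query: int
    n_control_lists: int
    matching_attempts: int
    n_query_predicted_targets: int
    enrichment: dict[str, EnrichmentStat]


class PositionalStage(_Strict):
    background_tier1: dict[str, float]
    background_tier2: dict[str, float]
    events_tier1: dict[str, float]
    events_tier2: dict[str, float]
    n_unassigned_events: int
    metagene_weight: dict[str, float]


class GeneSetStage(_Strict):
    n_sets: int
    n_significant: int


class Stages(_Strict):
    synthetic: SyntheticStage
    consensus: ConsensusStage
    overlap_permutation: dict[str, PermutationResult]
    interaction_filter: InteractionStage
    matched_enrichment: MatchedEnrichmentStage
    positional: PositionalStage
    gene_set_enrichment: Optional[GeneSetStage] = None


class RunSummary(_Strict):
    config: dict
    stages: Stages
    input_hashes: dict[str, str]
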