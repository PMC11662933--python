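"""Covariate-matched control gene lists and targeting-event enrichment.

To ask whether a query gene list (the consistently dysregulated genes)
carries more predicted snoRNA targeting events than expected, control lists
of the same size are drawn from the tested-gene universe by rejection
sampling: a candidate list is accepted only when two-sided Wilcoxon rank-sum
tests find no significant difference from the query in exonic length, GC
content, and mean normalized expression (all three p > alpha). The
enrichment of a summary statistic (mean/median/sum of per-gene event counts)
over the accepted lists gives a fold (observed / median of control values)
and a permutation-style p-value with a 1/k floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, TranscriptModel, exonic_gc
from .synthetic import CountMatrix

COVARIATES = ("length", "gc", "expression")


@dataclass
class MatchedLists:
    """k accepted control lists with their per-covariate Wilcoxon p-values."""

    lists: list[list[str]]
    pvalues: pd.DataFrame  # k rows x covariate columns
    alpha: float
    n_attempts: int

    def __post_init__(self) -> None:
        if len(self.lists) != len(self.pvalues):
            raise ValueError("one p-value row per accepted list required")


class MatchingError(RuntimeError):
    """Rejection sampling exhausted; message reports the failing covariates."""


def compute_covariates(
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
    expression: CountMatrix,
    retained: Optional[Mapping[str, Sequence[TranscriptModel]]] = None,
    neuron_samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Exonic length (bp), GC fraction and mean normalized expression per gene.

    Length and GC are computed over the union of exons of the retained
    transcripts (all transcripts when ``retained`` is None); expression is
    the mean library-size-normalized count over ``neuron_samples`` (all
    samples by default). Genes missing a sequence or absent from the count
    matrix are excluded.
    """
    norm = expression.normalized()
    if neuron_samples is not None:
        norm = norm[list(neuron_samples)]
    mean_expr = norm.mean(axis=1)
    rows = {}
    for gene in genes:
        seq = sequences.get(gene.gene_id)
        if seq is None or gene.gene_id not in mean_expr.index:
            continue
        txs = retained.get(gene.gene_id) if retained is not None else None
        if retained is not None and txs is None:
            continue
        length, gc = exonic_gc(gene, seq, txs)
        rows[gene.gene_id] = (length, gc, float(mean_expr[gene.gene_id]))
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(COVARIATES)
    )
    df.index.name = "gene_id"
    return df


def _covariate_pvalues(
    query_cov: pd.DataFrame,
    cand_cov: pd.DataFrame,
    log_expression: bool,
) -> dict[str, float]:
    ps = {}
    for cov in COVARIATES:
        x = query_cov[cov].to_numpy(dtype=float)
        y = cand_cov[cov].to_numpy(dtype=float)
        if cov == "expression" and log_expression:
            x = np.log2(x + 1.0)
            y = np.log2(y + 1.0)
        ps[cov] = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return ps


def sample_matched_lists(
    query: Sequence[str],
    covariates: pd.DataFrame,
    k: int = 100,
    m: Optional[int] = None,
    alpha: float = 0.05,
    max_iter: int = 10_000,
    seed: int = 0,
    log_expression: bool = True,
) -> MatchedLists:
    """Draw ``k`` control lists matched to the query on all three covariates.

    Candidates of size ``m`` (default |query|) are drawn without replacement
    from the covariate table's genes excluding the query; a candidate is
    accepted iff the two-sided Mann-Whitney (Wilcoxon rank-sum) p-value
    exceeds ``alpha`` for length, GC and expression. Seed-deterministic.
    Raises :class:`MatchingError` when ``max_iter`` draws cannot supply k
    lists, reporting the acceptance rate and the most-often-failing
    covariates.
    """
    query = list(query)
    m = len(query) if m is None else m
    if covariates.isna().any().any():
        raise ValueError("covariate table contains NA values")
    pool = covariates.index.difference(query)
    if len(pool) < m:
        raise ValueError(
            f"universe minus query has {len(pool)} genes; need at least {m}"
        )
    query_cov = covariates.loc[[g for g in query if g in covariates.index]]
    rng = np.random.default_rng(seed)
    pool_arr = np.array(sorted(pool))

    lists: list[list[str]] = []
    prows: list[dict[str, float]] = []
    fails = {c: 0 for c in COVARIATES}
    attempts = 0
    while len(lists) < k and attempts < max_iter:
        attempts += 1
        cand = pool_arr[rng.choice(len(pool_arr), size=m, replace=False)]
        ps = _covariate_pvalues(query_cov, covariates.loc[cand], log_expression)
        if all(p > alpha for p in ps.values()):
            lists.append(sorted(cand))
            prows.append(ps)
        else:
            for c, p in ps.items():
                if p <= alpha:
                    fails[c] += 1
    if len(lists) < k:
        rate = len(lists) / attempts if attempts else 0.0
        worst = ", ".join(
            f"{c} ({n}/{attempts} rejections)" for c, n in sorted(
                fails.items(), key=lambda kv: -kv[1]
            ) if n
        )
        raise MatchingError(
            f"matched-list sampling got {len(lists)}/{k} lists in {attempts} "
            f"draws (acceptance rate {rate:.3f}); failing covariates: {worst or 'none'}"
        )
    return MatchedLists(
        lists=lists,
        pvalues=pd.DataFrame(prows),
        alpha=alpha,
        n_attempts=attempts,
    )


def enrichment_vs_controls(
    query_counts: Mapping[str, int] | pd.Series,
    control_lists: MatchedLists | Sequence[Sequence[str]],
    per_gene_events: Mapping[str, int] | pd.Series,
    statistics: Sequence[str] = ("mean", "median", "sum"),
    fold_ref: str = "median",
) -> pd.DataFrame:
    """Enrichment of query targeting-event statistics over matched controls.

    For each statistic S, observed = S(query per-gene counts) and the null is
    {S(control-list counts)} over the k lists; fold = observed over the
    ``fold_ref`` (median by default) of the null, and p = #(null >= observed)/k
    floored at 1/k. Control genes missing from ``per_gene_events`` count 0.
    Returns a frame indexed by statistic with columns observed, null_ref,
    fold, p_value, p_is_floor.
    """
    lists = control_lists.lists if isinstance(control_lists, MatchedLists) else list(control_lists)
    k = len(lists)
    if k == 0:
        raise ValueError("no control lists supplied")
    events = pd.Series(per_gene_events, dtype=float)
    q = pd.Series(query_counts, dtype=float)

    funcs = {"mean": np.mean, "median": np.median, "sum": np.sum}
    rows = {}
    for stat in statistics:
        f = funcs[stat]
        observed = float(f(q.to_numpy()))
        null = np.array(
            [float(f(events.reindex(lst).fillna(0.0).to_numpy())) for lst in lists]
        )
        ref = float(np.median(null) if fold_ref == "median" else np.mean(null))
        fold = observed / ref if ref > 0 else float("inf") if observed > 0 else float("nan")
        count = int(np.count_nonzero(null >= observed))
        p, floor = (1.0 / k, True) if count == 0 else (count / k, False)
        rows[stat] = {
            "observed": observed,
            "null_ref": ref,
            "fold": fold,
            "p_value": p,
            "p_is_floor": floor,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
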