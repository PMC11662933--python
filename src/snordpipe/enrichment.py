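"""Gene-set over-representation statistics.

Hypergeometric upper-tail test of a query gene list against named gene-set
collections over a stated universe, Benjamini-Hochberg adjustment across the
tested sets, and the foldEnrichment score: GeneRatio (k/n) divided by
BgRatio (K/M). Records are ordered by adjusted p-value, then by
foldEnrichment descending.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def gene_set_enrichment(
    query: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One over-representation record per gene set.

    k = |query & set|, n = |query|, K = |set & universe|, M = |universe|;
    p is the hypergeometric upper tail P(X >= k); padj is BH across all
    tested sets; fold_enrichment = (k/n) / (K/M).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ValueError("query genes must be contained in the universe")
    n = len(q)
    M = len(uni)
    rows = []
    for set_id, members in collections.items():
        s = set(members) & uni
        K = len(s)
        k = len(q & s)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        gene_ratio = k / n if n else 0.0
        bg_ratio = K / M
        fold = gene_ratio / bg_ratio if bg_ratio > 0 else 0.0
        rows.append(
            {
                "set_id": set_id,
                "k_overlap": k,
                "query_size": n,
                "set_size": K,
                "universe_size": M,
                "p_value": p,
                "gene_ratio": gene_ratio,
                "bg_ratio": bg_ratio,
                "fold_enrichment": fold,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values(
            ["padj", "fold_enrichment"], ascending=[True, False]
        ).reset_index(drop=True)
    else:
        df["padj"] = pd.Series(dtype=float)
    return df
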