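"""Low-count filtering, significance calling and DEG consensus.

Implements the filtering ladder used to call a gene "consistently
dysregulated" in the isogenic deletion models: drop weakly covered genes,
keep padj < 0.05 calls split by log2FC sign, require agreement across the
three per-deletion statistical designs, then intersect the two deletion
models (optionally requiring concordant direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .synthetic import CountMatrix


@dataclass(frozen=True)
class DEGSet:
    """Directional significant-gene sets plus the tested-gene universe."""

    contrast_id: str
    universe: frozenset[str]
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(f"{self.contrast_id}: up and down sets overlap")
        if not (self.up | self.down) <= self.universe:
            raise ValueError(f"{self.contrast_id}: DEGs outside the universe")

    @property
    def all_degs(self) -> frozenset[str]:
        return self.up | self.down

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


def filter_low_counts(counts: CountMatrix | pd.DataFrame, min_mean: float) -> list[str]:
    """Gene ids whose mean count across all samples is >= ``min_mean``."""
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise ValueError("empty count matrix")
    keep = mat.mean(axis=1) >= min_mean
    return list(mat.index[keep])


def significant_degs(
    table: pd.DataFrame, contrast_id: str = "", padj_lt: float = 0.05
) -> DEGSet:
    """Call directional DEGs from a DE result table.

    up: padj < ``padj_lt`` and log2FC > 0; down: padj < ``padj_lt`` and
    log2FC < 0. Rows with missing padj, and log2FC exactly 0, are excluded
    from both directions. The universe is every row of the table.
    """
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicate gene_id(s) in DE table: {dupes[:5]}")
    padj = pd.to_numeric(table["padj"], errors="coerce")
    lfc = pd.to_numeric(table["log2FoldChange"], errors="coerce")
    sig = padj.notna() & (padj < padj_lt)
    up = table.loc[sig & (lfc > 0), "gene_id"]
    down = table.loc[sig & (lfc < 0), "gene_id"]
    return DEGSet(
        contrast_id=contrast_id,
        universe=frozenset(table["gene_id"]),
        up=frozenset(up),
        down=frozenset(down),
    )


def consensus_across_designs(
    degsets: Sequence[DEGSet],
    require_sign_consistency: bool = True,
    contrast_id: str = "consensus",
) -> DEGSet:
    """Genes significant in all three per-deletion designs.

    With sign consistency (default) a gene must carry the same direction in
    all three sets and that direction is carried into the consensus;
    without it, membership is by gene identifier only and the direction is
    taken from the first set (genes with conflicting directions across
    designs are then placed by the first design's call).
    """
    if len(degsets) != 3:
        raise ValueError(f"expected exactly 3 DEG sets, got {len(degsets)}")
    universe = frozenset.intersection(*(d.universe for d in degsets))
    if require_sign_consistency:
        up = frozenset.intersection(*(d.up for d in degsets)) & universe
        down = frozenset.intersection(*(d.down for d in degsets)) & universe
    else:
        shared = frozenset.intersection(*(d.all_degs for d in degsets)) & universe
        up = shared & degsets[0].up
        down = shared - up
    return DEGSet(contrast_id=contrast_id, universe=universe, up=up, down=down)


def shared_across_models(
    a: DEGSet,
    b: DEGSet,
    mode: Literal["any_direction", "concordant"] = "concordant",
) -> frozenset[str]:
    """Genes shared between two deletion models' DEG sets.

    ``any_direction`` intersects by identifier; ``concordant`` additionally
    requires the same direction in both models (always a subset of the
    former).
    """
    if mode == "any_direction":
        return a.all_degs & b.all_degs
    if mode == "concordant":
        return (a.up & b.up) | (a.down & b.down)
    raise ValueError(f"unknown mode {mode!r}")


def log2fc_pseudocount(
    counts: CountMatrix | pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_a + pc) / (mean_b + pc)); finite for every gene."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    mean_a = mat[ga].mean(axis=1)
    mean_b = mat[gb].mean(axis=1)
    return pd.Series(
        np.log2((mean_a + pseudocount) / (mean_b + pseudocount)),
        index=mat.index,
        name="log2fc",
    )
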