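"""Directional DEG-overlap permutation test.

The observed statistic is the number of genes called up in both contrasts
plus the number called down in both. The null is built by shuffling each
side's gene list and designating the first n_up genes "up" and the last
n_down genes "down" (matching the observed directional counts), then counting
the same directional overlap; this is repeated ``n_perm`` times (10 000 by
default). Enrichment is the observed count over the median permuted count.
The p-value counts permuted values >= observed; when none reach the observed
value it is reported as the upper bound 1/n_perm and flagged as a floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .consensus import DEGSet


@dataclass(frozen=True)
class PermutationSummary:
    observed: int
    null_values: np.ndarray
    n_perm: int
    fold: float  # observed / median(null); inf when the null median is 0
    p_value: float
    p_is_floor: bool
    null_median: float

    def __post_init__(self) -> None:
        if len(self.null_values) != self.n_perm:
            raise ValueError("null vector length must equal n_perm")


def observed_overlap(a: DEGSet, b: DEGSet) -> tuple[int, int, int]:
    """(n_up_shared, n_down_shared, n_total) directional overlap of two DEG sets."""
    n_up = len(a.up & b.up)
    n_down = len(a.down & b.down)
    return n_up, n_down, n_up + n_down


def permuted_overlaps(
    universe_a: Sequence[str],
    n_up_a: int,
    n_down_a: int,
    universe_b: Sequence[str],
    n_up_b: int,
    n_down_b: int,
    n_perm: int = 10_000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Null distribution of the directional overlap under label shuffling.

    Per replicate each universe is independently shuffled; the first n_up
    entries are designated up and the last n_down designated down, and the
    replicate's value is |up_a & up_b| + |down_a & down_b|. Seed-
    deterministic; returns an integer vector of length ``n_perm``.
    """
    ua = list(universe_a)
    ub = list(universe_b)
    for n_up, n_down, uni, side in (
        (n_up_a, n_down_a, ua, "a"),
        (n_up_b, n_down_b, ub, "b"),
    ):
        if n_up < 0 or n_down < 0 or n_up + n_down > len(uni):
            raise ValueError(
                f"side {side}: n_up + n_down ({n_up}+{n_down}) exceeds "
                f"universe size {len(uni)}"
            )
    if rng is None:
        rng = np.random.default_rng(seed)

    # integer codes over the shared gene space; genes private to one universe
    # can never overlap and get code -1
    common = {g: i for i, g in enumerate(set(ua) & set(ub))}
    code_a = np.array([common.get(g, -1) for g in ua], dtype=np.int64)
    code_b = np.array([common.get(g, -1) for g in ub], dtype=np.int64)
    n_common = len(common)

    out = np.empty(n_perm, dtype=np.int64)
    if n_common == 0:
        out[:] = 0
        return out

    # membership arrays over the common code space, reused per replicate:
    # 1 = up, -1 = down, 0 = neither
    lab_a = np.zeros(n_common, dtype=np.int8)
    for i in range(n_perm):
        perm_a = rng.permutation(code_a)
        perm_b = rng.permutation(code_b)
        up_a = perm_a[:n_up_a]
        down_a = perm_a[len(perm_a) - n_down_a :] if n_down_a else perm_a[:0]
        up_b = perm_b[:n_up_b]
        down_b = perm_b[len(perm_b) - n_down_b :] if n_down_b else perm_b[:0]
        lab_a[:] = 0
        lab_a[up_a[up_a >= 0]] = 1
        lab_a[down_a[down_a >= 0]] = -1
        ub_c = up_b[up_b >= 0]
        db_c = down_b[down_b >= 0]
        out[i] = int(np.count_nonzero(lab_a[ub_c] == 1)) + int(
            np.count_nonzero(lab_a[db_c] == -1)
        )
    return out


def summarize_permutation(
    observed: int, null_values: np.ndarray, n_perm: Optional[int] = None
) -> PermutationSummary:
    """Fold enrichment and permutation p-value for an observed overlap.

    p = #(null >= observed) / n_perm, with ties counting toward p; a zero
    count is reported as the upper bound 1/n_perm with ``p_is_floor`` set.
    Fold = observed / median(null); a zero median yields ``fold = inf``.
    """
    null_values = np.asarray(null_values)
    if n_perm is None:
        n_perm = len(null_values)
    if n_perm == 0:
        raise ValueError("n_perm must be positive")
    if len(null_values) != n_perm:
        raise ValueError("null vector length must equal n_perm")
    count = int(np.count_nonzero(null_values >= observed))
    if count == 0:
        p, floor = 1.0 / n_perm, True
    else:
        p, floor = count / n_perm, False
    med = float(np.median(null_values))
    fold = float(observed) / med if med > 0 else float("inf")
    return PermutationSummary(
        observed=int(observed),
        null_values=null_values,
        n_perm=int(n_perm),
        fold=fold,
        p_value=p,
        p_is_floor=floor,
        null_median=med,
    )


def overlap_permutation_test(
    a: DEGSet,
    b: DEGSet,
    n_perm: int = 10_000,
    seed: int = 0,
    shuffle_universe: bool = True,
) -> PermutationSummary:
    """Observed directional overlap of two DEG sets against its shuffled null.

    With ``shuffle_universe`` (default) each side's full tested-gene universe
    is shuffled; otherwise only the significant lists themselves are
    shuffled (the two readings of shuffling "lists of all DEGs").
    """
    _, _, observed = observed_overlap(a, b)
    if shuffle_universe:
        ua: Sequence[str] = sorted(a.universe)
        ub: Sequence[str] = sorted(b.universe)
    else:
        ua = sorted(a.all_degs)
        ub = sorted(b.all_degs)
    null = permuted_overlaps(
        ua, a.n_up, a.n_down, ub, b.n_up, b.n_down, n_perm=n_perm, seed=seed
    )
    return summarize_permutation(observed, null, n_perm)
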