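"""Consecutive-window filtering of snoRNA-target interaction scores.

snoGloBe-style predictions score a sliding duplex window between a snoRNA
copy and a target transcript. A predicted binding (targeting) event is kept
only when at least ``min_run`` consecutive windows — advancing by ``step`` nt
simultaneously on the snoRNA and the target (genomically rightward on ``+``
targets, leftward on ``-`` targets) — all score at or above ``threshold``
(the stringent setting recommended for snoGloBe predictions:
threshold 0.98, minimum run 3). A maximal qualifying
run becomes exactly one merged interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .snorna import SnoRNACopy, registry_index


@dataclass(frozen=True)
class FilterParams:
    """snoGloBe-recommended stringent defaults: score >= 0.98, >= 3 windows."""

    score_threshold: float = 0.98
    min_run: int = 3
    step: int = 1
    max_gap: int = 0  # tolerated missing windows between qualifying ones

    def __post_init__(self) -> None:
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must lie in [0, 1]")
        if self.min_run < 1 or self.step < 1 or self.max_gap < 0:
            raise ValueError("min_run/step must be >= 1 and max_gap >= 0")


@dataclass(frozen=True)
class Interaction:
    """One merged predicted binding event (a maximal qualifying window run)."""

    sno_id: str
    sno_start: int  # on the snoRNA, 0-based
    sno_end: int
    target_gene_id: str
    target: GenomicInterval
    n_windows: int
    min_score: float
    mean_score: float
    window_starts: tuple[int, ...] = ()  # sno-side starts (debug audit trail)

    @property
    def sno_center(self) -> int:
        return (self.sno_start + self.sno_end) // 2


def merge_consecutive_windows(
    windows: pd.DataFrame,
    params: FilterParams = FilterParams(),
    window_length: Optional[int] = None,
    keep_members: bool = False,
) -> list[Interaction]:
    """Merge per-window scores into predicted binding events.

    ``windows`` uses the canonical columns (sno_id, sno_start,
    target_gene_id, target_chrom, target_start, strand, score);
    ``window_length`` defaults to the table's ``attrs``. Windows are
    deduplicated by genomic coordinate, filtered at the score threshold, and
    maximal runs advancing by ``step`` on both coordinates (strand-
    appropriately on the target) of length >= ``min_run`` each yield one
    interaction spanning the run's extent on both sides. Duplicate
    (sno_id, sno_start, target_start) rows with conflicting scores are an
    error.
    """
    if window_length is None:
        window_length = windows.attrs.get("window_length")
        if window_length is None:
            raise ValueError("window_length not given and absent from table attrs")
    wl = int(window_length)

    dup = windows.duplicated(
        subset=["sno_id", "sno_start", "target_gene_id", "target_start"], keep=False
    )
    if dup.any():
        d = windows.loc[dup]
        if d.groupby(["sno_id", "sno_start", "target_gene_id", "target_start"])[
            "score"
        ].nunique().gt(1).any():
            raise ValueError("duplicate window rows with conflicting scores")
        windows = windows.drop_duplicates(
            subset=["sno_id", "sno_start", "target_gene_id", "target_start"]
        )

    passing = windows[windows["score"] >= params.score_threshold]
    out: list[Interaction] = []
    group_cols = ["sno_id", "target_gene_id", "target_chrom", "strand"]
    for (sno_id, gene_id, chrom, strand), grp in passing.groupby(
        group_cols, sort=True
    ):
        sign = 1 if strand == "+" else -1
        cells = {
            (int(s), int(t)): float(sc)
            for s, t, sc in zip(grp["sno_start"], grp["target_start"], grp["score"])
        }
        reach = params.step * (params.max_gap + 1)
        for (s0, t0) in sorted(cells):
            if _predecessor(cells, s0, t0, sign, params):
                continue  # not a run start
            run = [(s0, t0)]
            s, t = s0, t0
            while True:
                nxt = _successor(cells, s, t, sign, params)
                if nxt is None:
                    break
                s, t = nxt
                run.append(nxt)
            if len(run) < params.min_run:
                continue
            scores = [cells[c] for c in run]
            sno_lo = run[0][0]
            sno_hi = run[-1][0] + wl
            t_positions = [c[1] for c in run]
            t_lo = min(t_positions)
            t_hi = max(t_positions) + wl
            out.append(
                Interaction(
                    sno_id=sno_id,
                    sno_start=sno_lo,
                    sno_end=sno_hi,
                    target_gene_id=gene_id,
                    target=GenomicInterval(chrom, t_lo, t_hi, strand),
                    n_windows=len(run),
                    min_score=min(scores),
                    mean_score=float(np.mean(scores)),
                    window_starts=tuple(c[0] for c in run) if keep_members else (),
                )
            )
    out.sort(
        key=lambda x: (x.target.chrom, x.target.start, x.target.end, x.sno_id, x.sno_start)
    )
    return out


def _successor(cells, s, t, sign, params):
    for k in range(1, params.max_gap + 2):
        cand = (s + k * params.step, t + sign * k * params.step)
        if cand in cells:
            return cand
    return None


def _predecessor(cells, s, t, sign, params) -> bool:
    for k in range(1, params.max_gap + 2):
        if (s - k * params.step, t - sign * k * params.step) in cells:
            return True
    return False


def count_events(
    interactions: Iterable[Interaction],
    registry: Sequence[SnoRNACopy],
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Per-copy event counts, per-group totals and per-group per-copy means.

    Every registry copy appears in the per-copy counts (zero when unhit);
    group means divide by the full group size including zero-count copies.
    SNORD115 copies (no group) are tallied under group "SNORD115".
    """
    reg = registry_index(registry)
    counts = pd.Series(0, index=pd.Index([c.copy_id for c in registry], name="copy_id"))
    for x in interactions:
        if x.sno_id not in reg:
            raise KeyError(f"unknown snoRNA copy {x.sno_id}")
        counts[x.sno_id] += 1
    group_of = {
        c.copy_id: (c.group if c.group is not None else c.cluster) for c in registry
    }
    groups = counts.groupby(counts.index.map(group_of))
    totals = groups.sum()
    means = groups.mean()
    totals.index.name = means.index.name = "group"
    return counts, totals, means
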