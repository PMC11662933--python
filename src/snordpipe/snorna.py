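"""SNORD116 / SNORD115 snoRNA copy registry.

The PWS locus carries a tandem array of 30 SNORD116 C/D-box snoRNA copies,
split by sequence similarity into group I (copies 1-9), group II (copies
10-24) and group III (copies 25-30), plus 48 SNORD115 copies (no group
structure). Each copy carries the canonical C, D', C' and D boxes in 5'->3'
order; the second antisense element (ASE2) is the guide segment between the
3' end of the C' box and the 5' end of the D box.

Real copy lengths and box coordinates are not part of this package's inputs;
the registry built here uses configurable synthetic placeholders (length
~95 nt, boxes at canonical relative positions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .intervals import Span

SNORD116_GROUPS = {"I": range(1, 10), "II": range(10, 25), "III": range(25, 31)}
N_SNORD116 = 30
N_SNORD115 = 48


@dataclass(frozen=True)
class SnoRNACopy:
    """One snoRNA copy with box coordinates on the snoRNA (0-based)."""

    copy_id: str
    cluster: str  # SNORD116 | SNORD115
    group: Optional[str]  # I | II | III for SNORD116, None for SNORD115
    length: int
    box_c: Span
    box_dprime: Span
    box_cprime: Span
    box_d: Span

    def __post_init__(self) -> None:
        boxes = [self.box_c, self.box_dprime, self.box_cprime, self.box_d]
        for s, e in boxes:
            if not (0 <= s < e <= self.length):
                raise ValueError(f"{self.copy_id}: box {s}-{e} outside [0, {self.length})")
        for (_, e1), (s2, _) in zip(boxes, boxes[1:]):
            if e1 > s2:
                raise ValueError(f"{self.copy_id}: boxes out of 5'->3' order C<D'<C'<D")

    @property
    def ase2(self) -> Span:
        """Second antisense element: between the C' box and the D box."""
        return (self.box_cprime[1], self.box_d[0])


def snord116_group(index: int) -> str:
    for name, rng in SNORD116_GROUPS.items():
        if index in rng:
            return name
    raise ValueError(f"SNORD116 copy index {index} outside 1-30")


def _boxes_for_length(length: int) -> tuple[Span, Span, Span, Span]:
    # canonical relative placement: C near 5' end, D near 3' end,
    # D'/C' internal; ASE2 (C'->D gap) stays >= 20 nt for lengths >= 85
    c = (5, 12)
    dprime = (int(0.34 * length), int(0.34 * length) + 4)
    cprime = (int(0.56 * length), int(0.56 * length) + 7)
    d = (length - 7, length - 3)
    return c, dprime, cprime, d


def build_snorna_registry(
    seed: int = 0,
    length_range: tuple[int, int] = (90, 100),
) -> list[SnoRNACopy]:
    """Build the 30-copy SNORD116 + 48-copy SNORD115 registry.

    Copy lengths are drawn uniformly from ``length_range`` (seeded); box
    coordinates follow canonical relative positions for the drawn length.
    """
    rng = np.random.default_rng(seed)
    copies: list[SnoRNACopy] = []
    for i in range(1, N_SNORD116 + 1):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        c, dp, cp, d = _boxes_for_length(length)
        copies.append(
            SnoRNACopy(f"SNORD116-{i}", "SNORD116", snord116_group(i), length, c, dp, cp, d)
        )
    for i in range(1, N_SNORD115 + 1):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        c, dp, cp, d = _boxes_for_length(length)
        copies.append(SnoRNACopy(f"SNORD115-{i}", "SNORD115", None, length, c, dp, cp, d))
    return copies


def registry_index(registry: Iterable[SnoRNACopy]) -> dict[str, SnoRNACopy]:
    return {c.copy_id: c for c in registry}
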