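"""Decompose a motif-positive protein into repetitive blocks.

The block period is estimated from the spacing of greedily selected
non-overlapping motif matches; blocks are then tiled from the first anchor,
snapping each boundary to a nearby match anchor so that imperfect repeats
realign.  The per-block cysteine count includes *all* cysteines in the
block interval, so subtypes carrying extra cysteine pairs beyond the
six-cysteine motif report their full count (8 or 10).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .motif_scan import MotifMatch
from .seqdata import ProteinRecord

__all__ = ["RepeatBlockDecomposition", "decompose_repeats"]


@dataclass(frozen=True)
class RepeatBlockDecomposition:
    """Repeat-block tiling of one protein."""

    protein_id: str
    period: int
    blocks: tuple[tuple[int, int], ...]  # half-open intervals, ascending
    cys_per_block: tuple[int, ...]
    block_length_range: tuple[int, int]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def modal_cys_per_block(self) -> int | None:
        """Most frequent per-block cysteine count (ties -> smallest).

        Defined only when there are at least two blocks.
        """
        if len(self.blocks) < 2:
            return None
        counts = Counter(self.cys_per_block)
        top = max(counts.values())
        return min(c for c, k in counts.items() if k == top)

    @property
    def is_empty(self) -> bool:
        return not self.blocks


def _empty(protein_id: str) -> RepeatBlockDecomposition:
    return RepeatBlockDecomposition(
        protein_id=protein_id, period=0, blocks=(),
        cys_per_block=(), block_length_range=(0, 0),
    )


def decompose_repeats(
    record: ProteinRecord,
    matches: Sequence[MotifMatch],
    min_blocks: int = 2,
    tolerance: float = 0.25,
) -> RepeatBlockDecomposition:
    """Tile a protein into repeat blocks anchored at motif cysteines.

    Parameters
    ----------
    record : ProteinRecord
        Protein already scanned by :func:`serscan.motif_scan.find_cys_blocks`.
    matches : sequence of MotifMatch
        Its motif matches (possibly overlapping; possibly empty).
    min_blocks : int
        Fewer tiled blocks than this yields an empty decomposition.
    tolerance : float
        Relative deviation from the period allowed when snapping a block
        boundary to a match anchor; a larger deviation breaks the tiling.

    Returns
    -------
    RepeatBlockDecomposition
        Empty (no blocks) when the anchors do not tile consistently.
    """
    if not matches:
        return _empty(record.id)

    # Candidate periods come from differences over all pairs of match
    # anchors (not just successive greedy spacings: a match may anchor at a
    # trailing cysteine of a block as well as at its first).  Among the
    # most frequent differences, the winner is the one whose tiling gives
    # the most homogeneous per-block cysteine counts — this disambiguates
    # accidental sub-periods, e.g. a trailing anchor sitting exactly at
    # half the true block length.
    all_anchors = sorted({m.anchor for m in matches})
    if len(all_anchors) < 2:
        return _empty(record.id)
    diffs = Counter(
        b - a
        for i, a in enumerate(all_anchors)
        for b in all_anchors[i + 1 :]
    )
    top = max(diffs.values())
    candidates = sorted(s for s, k in diffs.items() if k >= max(2, 0.8 * top))
    if not candidates:
        candidates = sorted(s for s, k in diffs.items() if k == top)

    best: tuple | None = None
    for period in candidates:
        blocks = _tile(record, all_anchors, period, tolerance)
        if len(blocks) < min_blocks:
            continue
        counts = [record.sequence.count("C", s, e) for s, e in blocks]
        mean = sum(counts) / len(counts)
        var = sum((c - mean) ** 2 for c in counts) / len(counts)
        key = (-var, len(blocks), -period)
        if best is None or key > best[0]:
            best = (key, period, blocks, counts)
    if best is None:
        return _empty(record.id)

    _, period, blocks, counts = best
    lengths = [e - s for s, e in blocks]
    return RepeatBlockDecomposition(
        protein_id=record.id,
        period=period,
        blocks=tuple(blocks),
        cys_per_block=tuple(counts),
        block_length_range=(min(lengths), max(lengths)),
    )


def _tile(
    record: ProteinRecord,
    anchors: Sequence[int],
    period: int,
    tolerance: float,
) -> list[tuple[int, int]]:
    """Chain block starts from the first anchor at the given period.

    Each next boundary snaps to the match anchor closest to (previous
    start + period) within ``tolerance * period``; the chain stops when no
    anchor is close enough.  The final block gets the nominal period; a
    trailing partial block is dropped.
    """
    slack = tolerance * period
    starts = [anchors[0]]
    while True:
        target = starts[-1] + period
        best = None
        for a in anchors:
            if a <= starts[-1]:
                continue
            dev = abs(a - target)
            if dev <= slack and (best is None or dev < abs(best - target)):
                best = a
        if best is None:
            break
        starts.append(best)
    blocks = [(a, b) for a, b in zip(starts, starts[1:])]
    if starts[-1] + period <= len(record.sequence):
        blocks.append((starts[-1], starts[-1] + period))
    return blocks
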