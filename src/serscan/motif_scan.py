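"""Length-constrained cysteine-block motif scanner.

The motif is a run of ``n_cys`` cysteines C X.. C X. C X. C X. C X. C where
X is any residue except cysteine, the first inter-cysteine gap is long
(default: more than 5 residues), every other gap is at least one residue,
and the whole block spans at most ``window_max`` residues.  Because X
excludes cysteine, the cysteines of a match are necessarily consecutive
cysteines of the sequence, so the scan anchors on each cysteine and tests
the following run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .seqdata import ProteinRecord

__all__ = [
    "CysPatternParams",
    "MotifMatch",
    "ScreenResult",
    "find_cys_blocks",
    "screen_proteome",
    "saturation_scan",
]


@dataclass(frozen=True)
class CysPatternParams:
    """Grammar of the cysteine-block pattern.

    The default grammar (6 cysteines, first gap >= 6, other gaps >= 1 and
    unbounded, span <= 120) is the one that defines the candidate set.  The
    exploratory variant uses ``n_cys=4``, ``max_inner_gap=5`` and
    ``window_min=30``.
    """

    n_cys: int = 6
    min_first_gap: int = 6
    min_inner_gap: int = 1
    max_inner_gap: int | None = None
    window_max: int = 120
    window_min: int = 0

    def __post_init__(self) -> None:
        if self.n_cys not in (4, 6):
            raise ValueError(f"n_cys must be 4 or 6, got {self.n_cys}")
        if self.min_first_gap < 1:
            raise ValueError("min_first_gap must be >= 1")
        if self.min_inner_gap < 1:
            raise ValueError("min_inner_gap must be >= 1")
        if self.max_inner_gap is not None and self.max_inner_gap < self.min_inner_gap:
            raise ValueError("max_inner_gap must be >= min_inner_gap")
        if self.window_min > self.window_max:
            raise ValueError("window_min must be <= window_max")


@dataclass(frozen=True)
class MotifMatch:
    """One located cysteine block."""

    protein_id: str
    cys_positions: tuple[int, ...]

    @property
    def anchor(self) -> int:
        return self.cys_positions[0]

    @property
    def last(self) -> int:
        return self.cys_positions[-1]

    @property
    def span(self) -> int:
        """Inclusive residue span from first to last cysteine."""
        return self.cys_positions[-1] - self.cys_positions[0] + 1

    @property
    def gaps(self) -> tuple[int, ...]:
        """Residue counts strictly between consecutive cysteines."""
        return tuple(
            b - a - 1 for a, b in zip(self.cys_positions, self.cys_positions[1:])
        )


def find_cys_blocks(
    record: ProteinRecord, params: CysPatternParams | None = None
) -> list[MotifMatch]:
    """Find all cysteine-block matches in one protein.

    Every cysteine is tried as an anchor; the candidate block is the run of
    the next ``n_cys - 1`` cysteines.  Matches are reported in ascending
    anchor order and may overlap.
    """
    params = params or CysPatternParams()
    seq = record.sequence
    n = params.n_cys
    matches: list[MotifMatch] = []
    for anchor in range(len(seq)):
        if seq[anchor] != "C":
            continue
        # Walk the substring starting at this cysteine, collecting the next
        # cysteines while the window allows; bail out on the first violated
        # gap rule — later cysteines cannot repair it for this anchor.
        positions = [anchor]
        j = anchor + 1
        limit = min(len(seq), anchor + params.window_max)
        ok = True
        while len(positions) < n and j < limit:
            if seq[j] == "C":
                gap = j - positions[-1] - 1
                if len(positions) == 1:
                    if gap < params.min_first_gap:
                        ok = False
                        break
                else:
                    if gap < params.min_inner_gap:
                        ok = False
                        break
                    if params.max_inner_gap is not None and gap > params.max_inner_gap:
                        ok = False
                        break
                positions.append(j)
            j += 1
        if ok and len(positions) == n:
            span = positions[-1] - positions[0] + 1
            if params.window_min <= span <= params.window_max:
                matches.append(
                    MotifMatch(protein_id=record.id, cys_positions=tuple(positions))
                )
    return matches


@dataclass
class ScreenResult:
    """Per-protein match lists plus the set of pattern-positive ids."""

    matches: dict[str, list[MotifMatch]]
    hit_ids: list[str]

    @property
    def n_hits(self) -> int:
        return len(self.hit_ids)


def screen_proteome(
    records: Sequence[ProteinRecord], params: CysPatternParams | None = None
) -> ScreenResult:
    """Scan a proteome; a protein is a hit if it has at least one match.

    Hit order follows input order (deterministic).  Duplicate ids are an
    error.
    """
    params = params or CysPatternParams()
    seen: set[str] = set()
    matches: dict[str, list[MotifMatch]] = {}
    hit_ids: list[str] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        m = find_cys_blocks(rec, params)
        matches[rec.id] = m
        if m:
            hit_ids.append(rec.id)
    return ScreenResult(matches=matches, hit_ids=hit_ids)


def saturation_scan(
    records: Sequence[ProteinRecord], param_grid: Sequence[CysPatternParams]
) -> pd.DataFrame:
    """Hit counts over a grid of pattern parameters, one row per grid point."""
    if len(param_grid) == 0:
        raise ValueError("empty parameter grid")
    rows = []
    for p in param_grid:
        result = screen_proteome(records, p)
        rows.append(
            {
                "n_cys": p.n_cys,
                "min_first_gap": p.min_first_gap,
                "min_inner_gap": p.min_inner_gap,
                "max_inner_gap": p.max_inner_gap,
                "window_min": p.window_min,
                "window_max": p.window_max,
                "n_hits": result.n_hits,
            }
        )
    return pd.DataFrame(rows)
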