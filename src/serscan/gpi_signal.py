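"""Rule-based GPI-anchor signal classifier.

Evaluates the canonical tripartite C-terminal anchor signal: a small
attachment residue (the omega site), a polar spacer at omega+3..omega+8,
and a hydrophobic tail from omega+9 to the C-terminus.  The classifier is
a deterministic checklist over Kyte-Doolittle hydropathy — it preserves
the class vocabulary of HMM-based predictors (highly probable / probable /
weakly probable / none) but is not a reproduction of any trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .seqdata import ProteinRecord

__all__ = [
    "KYTE_DOOLITTLE",
    "GpiParams",
    "GpiSignal",
    "score_gpi_signal",
    "filter_candidates",
]

#: Kyte-Doolittle hydropathy index; X (unknown) is neutral.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: Maximum of the scale; used to normalize the tail-hydropathy margin.
_KD_MAX = 4.5


@dataclass(frozen=True)
class GpiParams:
    """Thresholds of the rule-based GPI signal checklist."""

    omega_residues: frozenset[str] = frozenset("GASNDC")
    #: allowed distance (residue count) from omega to the C-terminus
    omega_search_window: tuple[int, int] = (11, 34)
    spacer_offsets: tuple[int, int] = (3, 8)
    min_polar_spacer: int = 4
    min_tail_len: int = 8
    min_tail_hydropathy: float = 1.0
    hydropathy_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE)
    )

    def __post_init__(self) -> None:
        lo, hi = self.omega_search_window
        if lo < 1 or lo > hi:
            raise ValueError("omega_search_window must satisfy 1 <= lo <= hi")
        if self.spacer_offsets[0] > self.spacer_offsets[1]:
            raise ValueError("spacer_offsets must be ordered")
        missing = set("ACDEFGHIKLMNPQRSTVWYX") - set(self.hydropathy_scale)
        if missing:
            raise ValueError(f"hydropathy scale missing residues: {sorted(missing)}")


@dataclass(frozen=True)
class GpiSignal:
    """Parsed anchor-signal anatomy with a class label."""

    omega_index: int | None
    spacer_polar_count: int
    tail_len: int
    tail_hydropathy: float
    score: float
    gpi_class: str  # highly_probable | probable | weakly_probable | none


_NONE = GpiSignal(
    omega_index=None, spacer_polar_count=0, tail_len=0,
    tail_hydropathy=0.0, score=0.0, gpi_class="none",
)


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else 1.0 if x > 1.0 else x


def score_gpi_signal(
    record: ProteinRecord, params: GpiParams | None = None
) -> GpiSignal:
    """Evaluate every admissible omega position and report the best candidate.

    A candidate omega passes the hard rules iff its residue is in the
    allowed set, at least ``min_polar_spacer`` of the six spacer residues
    have negative hydropathy, the tail has at least ``min_tail_len``
    residues and its mean hydropathy reaches ``min_tail_hydropathy``.  The
    score is the mean of three margins (spacer polarity fraction, tail
    hydropathy above threshold, tail length above threshold), each clipped
    to [0, 1]; classes: >= 0.5 highly_probable, >= 0.25 probable, else
    weakly_probable.  If no omega passes, the class is ``none``.
    """
    params = params or GpiParams()
    seq = record.sequence
    kd = params.hydropathy_scale
    n = len(seq)
    lo, hi = params.omega_search_window
    s_lo, s_hi = params.spacer_offsets
    tail_start_off = s_hi + 1  # hydrophobic region begins right after the spacer

    best: GpiSignal | None = None
    for dist in range(lo, hi + 1):  # residues strictly after omega
        i = n - 1 - dist
        if i < 1:  # omega needs at least one upstream body residue
            break
        if seq[i] not in params.omega_residues:
            continue
        spacer = seq[i + s_lo : i + s_hi + 1]
        if len(spacer) < (s_hi - s_lo + 1):
            continue
        polar = sum(1 for c in spacer if kd[c] < 0.0)
        tail = seq[i + tail_start_off :]
        tail_len = len(tail)
        if tail_len == 0:
            continue
        tail_kd = sum(kd[c] for c in tail) / tail_len
        passes = (
            polar >= params.min_polar_spacer
            and tail_len >= params.min_tail_len
            and tail_kd >= params.min_tail_hydropathy
        )
        if not passes:
            continue
        m_polar = polar / (s_hi - s_lo + 1)
        m_kd = (tail_kd - params.min_tail_hydropathy) / (
            _KD_MAX - params.min_tail_hydropathy
        )
        m_len = (tail_len - params.min_tail_len) / params.min_tail_len
        score = (_clip01(m_polar) + _clip01(m_kd) + _clip01(m_len)) / 3.0
        sig = GpiSignal(
            omega_index=i,
            spacer_polar_count=polar,
            tail_len=tail_len,
            tail_hydropathy=tail_kd,
            score=score,
            gpi_class=_classify(score),
        )
        if best is None or sig.score > best.score:
            best = sig
    return best if best is not None else _NONE


def _classify(score: float) -> str:
    if score >= 0.5:
        return "highly_probable"
    if score >= 0.25:
        return "probable"
    return "weakly_probable"


def filter_candidates(
    records: Sequence[ProteinRecord], params: GpiParams | None = None
) -> list[ProteinRecord]:
    """Keep records classified highly_probable, preserving input order."""
    params = params or GpiParams()
    return [
        rec for rec in records
        if score_gpi_signal(rec, params).gpi_class == "highly_probable"
    ]
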