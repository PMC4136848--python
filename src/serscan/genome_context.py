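"""Tandem-array detection on scaffolds and summary statistics.

Adjacency is measured in gene rank (position in the scaffold's gene
order), not base pairs: two candidates are in the same array when at most
``max_intervening`` non-candidate genes separate them.  Singletons are not
arrays.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .seqdata import GeneLocus

__all__ = ["TandemArray", "detect_tandem_arrays", "tandem_summary"]


@dataclass
class TandemArray:
    """A run of >= 2 candidate genes in scaffold gene order."""

    scaffold_id: str
    member_ids: list[str]  # ordered by start coordinate
    subtype_composition: Counter
    n_intervening: int
    orientation_consistent: bool

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def is_pure(self) -> bool:
        """True when all assigned members share one subtype."""
        return len(self.subtype_composition) <= 1


def detect_tandem_arrays(
    loci: Sequence[GeneLocus],
    candidate_ids: Sequence[str] | set[str],
    max_intervening: int = 1,
    assignments: Mapping[str, str] | None = None,
) -> list[TandemArray]:
    """Find maximal candidate runs per scaffold.

    Parameters
    ----------
    loci : sequence of GeneLocus
        All genes (candidates and others); sorted internally per scaffold.
    candidate_ids : collection of str
        Ids of candidate genes; every candidate must have a locus.
    max_intervening : int
        Maximum number of non-candidate genes tolerated between two
        consecutive candidates of the same array.
    assignments : mapping, optional
        candidate id -> subtype, used to fill the subtype composition.
    """
    candidate_ids = set(candidate_ids)
    assignments = assignments or {}
    locus_ids = {l.gene_id for l in loci}
    missing = candidate_ids - locus_ids
    if missing:
        raise ValueError(f"candidates with no locus: {sorted(missing)}")

    by_scaffold: dict[str, list[GeneLocus]] = {}
    for l in loci:
        by_scaffold.setdefault(l.scaffold_id, []).append(l)

    arrays: list[TandemArray] = []
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda l: (l.start, l.end))
        run: list[GeneLocus] = []
        gap = 0
        intervening = 0

        def flush() -> None:
            nonlocal intervening
            if len(run) >= 2:
                members = [g.gene_id for g in run]
                comp = Counter(
                    assignments[m] for m in members if m in assignments
                )
                strands = {g.strand for g in run}
                arrays.append(
                    TandemArray(
                        scaffold_id=scaffold,
                        member_ids=members,
                        subtype_composition=comp,
                        n_intervening=intervening,
                        orientation_consistent=len(strands) == 1,
                    )
                )
            run.clear()
            intervening = 0

        for g in genes:
            if g.gene_id in candidate_ids:
                if run and gap > max_intervening:
                    flush()
                if run:
                    intervening += gap
                run.append(g)
                gap = 0
            else:
                gap += 1
        flush()
    return arrays


def tandem_summary(
    arrays: Sequence[TandemArray],
    all_candidates: Sequence[str] | set[str],
    assignments: Mapping[str, str] | None = None,
) -> dict:
    """Summary statistics of the tandem organization.

    Reports the fraction of candidates sitting in arrays, the number of
    scaffolds carrying arrays, per-array purity and the fraction of arrays
    whose members all share one strand.
    """
    all_candidates = set(all_candidates)
    in_arrays = {m for a in arrays for m in a.member_ids}
    n_total = len(all_candidates)
    n_arrays = len(arrays)
    pure = sum(1 for a in arrays if a.is_pure)
    consistent = sum(1 for a in arrays if a.orientation_consistent)
    return {
        "n_candidates": n_total,
        "n_arrays": n_arrays,
        "n_in_arrays": len(in_arrays),
        "n_singletons": n_total - len(in_arrays),
        "tandem_fraction": (len(in_arrays) / n_total) if n_total else 0.0,
        "n_scaffolds_with_arrays": len({a.scaffold_id for a in arrays}),
        "n_pure_arrays": pure,
        "n_mixed_arrays": n_arrays - pure,
        "orientation_consistent_fraction": (
            consistent / n_arrays if n_arrays else 0.0
        ),
    }
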