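"""Distance-based phylogeny and clade-based subtype assignment.

Contains a small progressive multiple aligner (sum-of-pairs profile
alignment along a neighbor-joining guide tree), p/Poisson distance
computation, a neighbor-joining tree builder with deterministic
tie-breaking, non-parametric bootstrap supports, and the clade rule that
assigns candidate sequences to reference subtypes (plain or starred).

The aligner is intentionally simple: classification downstream depends on
clade structure, not on matching any particular aligner's output
column-for-column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqdata import AMINO_ACIDS, ProteinRecord, ReferenceSet

__all__ = [
    "MSA",
    "DistanceMatrix",
    "PhyloTree",
    "SubtypeAssignment",
    "pairwise_align",
    "align_msa",
    "distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "assign_subtypes",
]

logger = logging.getLogger("serscan.phylo")

_GAP = "-"
_ALPHA = AMINO_ACIDS + "X" + _GAP  # column symbol order used by profiles


# ---------------------------------------------------------------------------
# Alignment


@dataclass
class MSA:
    """A multiple sequence alignment: equal-length rows over residues + '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows must all have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in MSA")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def resample_columns(self, indices: Sequence[int]) -> "MSA":
        rows = ["".join(r[i] for i in indices) for r in self.rows]
        return MSA(ids=list(self.ids), rows=rows)


def _substitution_matrix(name: str) -> np.ndarray:
    """Dense (len(_ALPHA) x len(_ALPHA)) score matrix; X and gap score 0."""
    sub = substitution_matrices.load(name)
    m = np.zeros((len(_ALPHA), len(_ALPHA)))
    for i, a in enumerate(_ALPHA):
        for j, b in enumerate(_ALPHA):
            if a in sub.alphabet and b in sub.alphabet:
                m[i, j] = sub[a, b]
    # X and gap columns stay neutral (0) against everything
    for i, a in enumerate(_ALPHA):
        if a in ("X", _GAP):
            m[i, :] = 0.0
            m[:, i] = 0.0
    return m


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Column symbol-frequency profile, shape (n_cols, len(_ALPHA))."""
    idx = {c: k for k, c in enumerate(_ALPHA)}
    L = len(rows[0])
    prof = np.zeros((L, len(_ALPHA)))
    for r in rows:
        for j, c in enumerate(r):
            prof[j, idx[c]] += 1.0
    prof /= len(rows)
    return prof


_NEG_INF = -1e30


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    sub: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Affine-gap (Gotoh) global alignment of two profiles.

    The first gapped position costs ``gap_open``; each further position in
    the same run costs ``gap_extend``.  Column-column score is the expected
    pairwise substitution score between the two frequency profiles.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = pa @ sub @ pb.T  # (La, Lb)
    La, Lb = S.shape

    M = np.full((La + 1, Lb + 1), _NEG_INF)
    Ix = np.full((La + 1, Lb + 1), _NEG_INF)  # gap in b (vertical move)
    Iy = np.full((La + 1, Lb + 1), _NEG_INF)  # gap in a (horizontal move)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, Lb + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend

    for i in range(1, La + 1):
        Mi1, Ixi1, Iyi1 = M[i - 1], Ix[i - 1], Iy[i - 1]
        M[i, 1:] = S[i - 1] + np.maximum.reduce(
            [Mi1[:-1], Ixi1[:-1], Iyi1[:-1]]
        )
        Ix[i, 1:] = np.maximum(
            np.maximum(Mi1[1:], Iyi1[1:]) - gap_open, Ixi1[1:] - gap_extend
        )
        # Iy needs a left-to-right scan within the row
        row_m, row_ix, row_iy = M[i], Ix[i], Iy[i]
        for j in range(1, Lb + 1):
            row_iy[j] = max(
                max(row_m[j - 1], row_ix[j - 1]) - gap_open,
                row_iy[j - 1] - gap_extend,
            )

    # Traceback
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = La, Lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # match column
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:  # gap in b
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k in range(len(rows_b)):
                out_b[k].append(_GAP)
            if abs(Ix[i, j] - (Ix[i - 1, j] - gap_extend)) < eps:
                state = 1
            elif abs(Ix[i, j] - (M[i - 1, j] - gap_open)) < eps:
                state = 0
            else:
                state = 2
            i -= 1
        else:  # gap in a
            for k in range(len(rows_a)):
                out_a[k].append(_GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            if abs(Iy[i, j] - (Iy[i, j - 1] - gap_extend)) < eps:
                state = 2
            elif abs(Iy[i, j] - (M[i, j - 1] - gap_open)) < eps:
                state = 0
            else:
                state = 1
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return (
        ["".join(reversed(c)) for c in out_a],
        ["".join(reversed(c)) for c in out_b],
    )


def pairwise_align(
    a: str,
    b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
) -> tuple[str, str]:
    """Global affine-gap alignment of two sequences (Gotoh)."""
    sub = _substitution_matrix(substitution_matrix)
    ra, rb = _align_profiles([a], [b], sub, gap_open, gap_extend)
    return ra[0], rb[0]


def _guide_distances(
    records: Sequence[ProteinRecord],
    substitution_matrix: str,
    gap_open: float,
    gap_extend: float,
) -> "DistanceMatrix":
    """1 - identity over global pairwise alignments (fast C aligner)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    n = len(records)
    d = np.zeros((n, n))
    seqs = [r.sequence.replace("X", "A") for r in records]  # matrix lacks X
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]
            counts = aln.counts()
            ident = counts.identities / aln.length if aln.length else 0.0
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(taxa=[r.id for r in records], d=d)


def align_msa(
    records: Sequence[ProteinRecord],
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
    length_filter: float = 5.0,
) -> MSA:
    """Progressive multiple alignment along an NJ guide tree.

    Sequences longer than ``length_filter`` times the median length cannot
    be aligned sensibly and are excluded with a logged warning.
    """
    records = list(records)
    if len(records) >= 2 and length_filter:
        med = median(len(r) for r in records)
        keep = []
        for r in records:
            if len(r) > length_filter * med:
                logger.warning(
                    "excluding %s from alignment: length %d exceeds %.0fx the "
                    "median (%d)", r.id, len(r), length_filter, med,
                )
            else:
                keep.append(r)
        records = keep
    if len(records) < 2:
        raise ValueError("alignment requires at least 2 sequences")

    sub = _substitution_matrix(substitution_matrix)
    if len(records) == 2:
        ra, rb = _align_profiles(
            [records[0].sequence], [records[1].sequence], sub, gap_open, gap_extend
        )
        return MSA(ids=[records[0].id, records[1].id], rows=[ra[0], rb[0]])

    guide_d = _guide_distances(records, substitution_matrix, gap_open, gap_extend)
    guide = nj_tree(guide_d)
    by_id = {r.id: r for r in records}

    def merge(node: "_Node") -> tuple[list[str], list[str]]:
        if node.label is not None:
            return [node.label], [by_id[node.label].sequence]
        ids: list[str] = []
        rows: list[str] = []
        for child, _ in node.children:
            cids, crows = merge(child)
            if not ids:
                ids, rows = cids, crows
            else:
                rows, crows = _align_profiles(rows, crows, sub, gap_open, gap_extend)
                ids, rows = ids + cids, rows + crows
        return ids, rows

    ids, rows = merge(guide.root)
    # restore input order for determinism and convenience
    order = sorted(range(len(ids)), key=lambda k: [r.id for r in records].index(ids[k]))
    return MSA(ids=[ids[k] for k in order], rows=[rows[k] for k in order])


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, finite distance matrix over named taxa."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise ValueError("distance matrix has negative entries")


def _encode_msa(msa: MSA) -> np.ndarray:
    idx = {c: k for k, c in enumerate(_ALPHA)}
    gap_code = idx[_GAP]
    arr = np.empty((len(msa.rows), msa.n_cols), dtype=np.uint8)
    for i, r in enumerate(msa.rows):
        arr[i] = [idx[c] for c in r]
    return arr


def distance_matrix(
    msa: MSA, model: str = "p", max_distance: float = 10.0
) -> DistanceMatrix:
    """Pairwise p-distances (or Poisson-corrected) from an MSA.

    p = mismatches / shared non-gap columns; poisson = -ln(1 - p), capped
    at ``max_distance`` as p approaches 1.  A pair with no shared non-gap
    column is an error.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    arr = _encode_msa(msa)
    gap_code = _ALPHA.index(_GAP)
    nongap = arr != gap_code
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        shared = nongap[i] & nongap[i + 1 :]
        n_shared = shared.sum(axis=1)
        if np.any(n_shared == 0):
            j = int(np.argmax(n_shared == 0)) + i + 1
            raise ValueError(
                f"no shared non-gap columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
            )
        mism = ((arr[i] != arr[i + 1 :]) & shared).sum(axis=1)
        d[i, i + 1 :] = mism / n_shared
    d = d + d.T
    if model == "poisson":
        with np.errstate(divide="ignore"):
            d = np.where(d >= 1.0, max_distance, -np.log1p(-np.minimum(d, 1.0 - 1e-12)))
        d = np.minimum(d, max_distance)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa=list(msa.ids), d=d)


# ---------------------------------------------------------------------------
# Neighbor joining


class _Node:
    """Light tree node: leaf iff ``label`` is set; children carry lengths."""

    __slots__ = ("label", "children", "min_leaf")

    def __init__(self, label: str | None = None,
                 children: list[tuple["_Node", float]] | None = None):
        self.label = label
        self.children = children or []
        self.min_leaf = label  # lexicographically smallest descendant leaf

    def leaves(self) -> list[str]:
        if self.label is not None:
            return [self.label]
        out: list[str] = []
        stack = [self]
        while stack:
            nd = stack.pop()
            if nd.label is not None:
                out.append(nd.label)
            else:
                stack.extend(c for c, _ in nd.children)
        return out

    def newick(self, supports: Mapping[frozenset, float] | None = None,
               taxa: frozenset | None = None, anchor: str | None = None) -> str:
        def fmt(node: "_Node", length: float | None) -> str:
            if node.label is not None:
                body = node.label
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                if supports is not None and taxa is not None:
                    bip = _canonical(frozenset(node.leaves()), taxa, anchor)
                    if bip in supports:
                        label = str(int(round(supports[bip])))
                body = f"({inner}){label}"
            if length is None:
                return body
            return f"{body}:{length:.6f}"

        return fmt(self, None) + ";"


def _canonical(side: frozenset, taxa: frozenset, anchor: str | None) -> frozenset:
    """Canonical form of a bipartition: the side not containing the anchor."""
    if anchor is None:
        anchor = min(taxa)
    return frozenset(taxa - side) if anchor in side else frozenset(side)


@dataclass
class PhyloTree:
    """Unrooted NJ tree with optional per-internal-edge bootstrap supports."""

    root: _Node
    taxa: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxon_set(self) -> frozenset:
        return frozenset(self.taxa)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, canonicalized on the anchor taxon."""
        taxa = self.taxon_set
        anchor = min(taxa)
        out: set[frozenset] = set()
        stack = [c for c, _ in self.root.children]
        while stack:
            nd = stack.pop()
            if nd.label is not None:
                continue
            side = frozenset(nd.leaves())
            if 1 < len(side) < len(taxa) - 1:
                out.add(_canonical(side, taxa, anchor))
            stack.extend(c for c, _ in nd.children)
        return out

    def newick(self) -> str:
        return self.root.newick(
            supports=self.supports or None,
            taxa=self.taxon_set,
            anchor=min(self.taxon_set),
        )

    def support_of(self, leafset: frozenset) -> float:
        """Support of the edge defining ``leafset``; trivial edges are 100."""
        taxa = self.taxon_set
        if len(leafset) <= 1 or len(leafset) >= len(taxa) - 1:
            return 100.0
        bip = _canonical(leafset, taxa, min(taxa))
        return self.supports.get(bip, 100.0 if not self.supports else 0.0)


def _nj(d: np.ndarray, labels: Sequence[str]) -> _Node:
    """Saitou-Nei neighbor joining with deterministic tie-breaking."""
    nodes = [_Node(label=l) for l in labels]
    keys = list(labels)  # tie-break key: smallest descendant leaf label
    d = d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-10)
        best = min(
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in cand if i < j
        )
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        new.min_leaf = min(keys[i], keys[j])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [new.min_leaf]
        d = d2

    if len(nodes) == 3:
        la = max(0.0, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
        lb = max(0.0, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
        lc = max(0.0, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
        root = _Node(children=[(nodes[0], la), (nodes[1], lb), (nodes[2], lc)])
    else:  # exactly 2 active nodes (cannot happen for n >= 3 input)
        root = _Node(children=[(nodes[0], d[0, 1] / 2), (nodes[1], d[0, 1] / 2)])
    root.min_leaf = min(n.min_leaf for n, _ in root.children)
    return root


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree; requires at least 3 taxa.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster) taxon pair, so the topology is deterministic and invariant
    to input order.
    """
    if len(D.taxa) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    root = _nj(D.d, D.taxa)
    return PhyloTree(root=root, taxa=list(D.taxa))


def bootstrap_supports(
    msa: MSA,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "p",
    max_distance: float = 10.0,
) -> PhyloTree:
    """NJ tree from ``msa`` with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each original internal
    bipartition.  Deterministic under a fixed seed; invariant to taxon
    input order (resampling depends only on the column count).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(distance_matrix(msa, model=model, max_distance=max_distance))
    original = tree.bipartitions()
    counts = {bip: 0 for bip in original}
    rng = np.random.default_rng(seed)
    L = msa.n_cols
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        rep = msa.resample_columns(idx.tolist())
        rep_tree = nj_tree(
            distance_matrix(rep, model=model, max_distance=max_distance)
        )
        for bip in rep_tree.bipartitions():
            if bip in counts:
                counts[bip] += 1
    tree.supports = {
        bip: 100.0 * c / n_replicates for bip, c in counts.items()
    }
    return tree


# ---------------------------------------------------------------------------
# Subtype assignment


@dataclass(frozen=True)
class SubtypeAssignment:
    """A candidate's clade-based subtype call."""

    candidate_id: str
    subtype: str  # e.g. H, L, J, H*, L*, J*, or 'unclassified'
    support: float | None


def _midpoint_root(tree: PhyloTree) -> _Node:
    """Midpoint-rooted copy of the tree (rooted on the longest leaf path)."""
    import dendropy

    dt = dendropy.Tree.get(data=tree.root.newick(), schema="newick",
                           preserve_underscores=True)
    dt.reroot_at_midpoint(update_bipartitions=False)

    def convert(node) -> _Node:
        if node.is_leaf():
            return _Node(label=node.taxon.label if node.taxon else node.label)
        children = []
        for ch in node.child_nodes():
            length = ch.edge.length if ch.edge.length is not None else 0.0
            children.append((convert(ch), float(length)))
        return _Node(children=children)

    return convert(dt.seed_node)


def assign_subtypes(
    tree: PhyloTree,
    refs: ReferenceSet,
    min_support: float = 40.0,
) -> list[SubtypeAssignment]:
    """Assign each non-reference leaf to a subtype via the clade rule.

    The tree is midpoint rooted.  For each candidate, the smallest clade
    containing it and at least one reference decides: if all references in
    that clade share one subtype and the clade's edge support reaches
    ``min_support``, the candidate gets that subtype.  Otherwise, if the
    candidate's maximal reference-free clade is sister to a clade whose
    references are pure for one subtype and whose edge support reaches
    ``min_support``, the candidate gets the starred variant of that
    subtype.  Anything else is unclassified.
    """
    leaf_set = set(tree.taxa)
    missing = [r for r in refs.labels if r not in leaf_set]
    if missing:
        raise ValueError(f"reference taxa absent from tree: {sorted(missing)}")
    ref_labels = refs.labels
    candidates = [t for t in tree.taxa if t not in ref_labels]

    rooted = _midpoint_root(tree)

    # parent map + cached leaf sets
    parent: dict[int, _Node] = {}
    leafsets: dict[int, frozenset] = {}

    def walk(node: _Node) -> frozenset:
        if node.label is not None:
            ls = frozenset([node.label])
        else:
            acc: set[str] = set()
            for ch, _ in node.children:
                parent[id(ch)] = node
                acc |= walk(ch)
            ls = frozenset(acc)
        leafsets[id(node)] = ls
        return ls

    walk(rooted)
    leaf_nodes = {}

    def collect(node: _Node) -> None:
        if node.label is not None:
            leaf_nodes[node.label] = node
        for ch, _ in node.children:
            collect(ch)

    collect(rooted)

    out: list[SubtypeAssignment] = []
    for cand in candidates:
        node = leaf_nodes[cand]
        # Ancestor chain whose reference content stays pure for one subtype;
        # the assignment support is the best-supported such clade (the base
        # of a clean subtype group is typically the strongly supported edge,
        # while small clades inside the group resolve arbitrarily).
        prev = node
        ref_free_top = node  # maximal reference-free clade containing cand
        pure_chain: list[tuple[frozenset, str]] = []
        first_ref_anc: _Node | None = None
        chain_subtype: str | None = None
        while id(prev) in parent:
            anc = parent[id(prev)]
            clade = leafsets[id(anc)]
            clade_refs = [r for r in clade if r in ref_labels]
            if not clade_refs:
                ref_free_top = anc
                prev = anc
                continue
            subtypes = {ref_labels[r] for r in clade_refs}
            if first_ref_anc is None:
                first_ref_anc = anc
            if len(subtypes) == 1 and (
                chain_subtype is None or subtypes == {chain_subtype}
            ):
                chain_subtype = next(iter(subtypes))
                pure_chain.append((clade, chain_subtype))
                prev = anc
                continue
            break

        assignment: SubtypeAssignment | None = None
        if pure_chain:
            best_clade, subtype = max(
                pure_chain, key=lambda cs: (tree.support_of(cs[0]), -len(cs[0]))
            )
            support = tree.support_of(best_clade)
            if support >= min_support:
                assignment = SubtypeAssignment(cand, subtype, support)

        if assignment is None and first_ref_anc is not None:
            # starred rule: the candidate's maximal reference-free clade is
            # sister to a clade whose references are pure for one subtype
            starred: list[SubtypeAssignment] = []
            for sib, _ in first_ref_anc.children:
                if sib is ref_free_top:
                    continue
                sibset = leafsets[id(sib)]
                sib_refs = [r for r in sibset if r in ref_labels]
                sib_subtypes = {ref_labels[r] for r in sib_refs}
                sib_support = tree.support_of(sibset)
                if len(sib_subtypes) == 1 and sib_support >= min_support:
                    starred.append(
                        SubtypeAssignment(cand, sib_subtypes.pop() + "*", sib_support)
                    )
            if len({a.subtype for a in starred}) == 1:
                assignment = starred[0]

        if assignment is None:
            assignment = SubtypeAssignment(cand, "unclassified", None)
        out.append(assignment)
    return out
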