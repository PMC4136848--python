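from __future__ import annotations

import math

import numpy as np
import pytest

from serscan.phylo_classify import (
    MSA,
    DistanceMatrix,
    align_msa,
    assign_subtypes,
    bootstrap_supports,
    distance_matrix,
    nj_tree,
    pairwise_align,
)
from serscan.seqdata import ProteinRecord, ReferenceSet

from oracles import global_alignment_bruteforce, random_additive_tree

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    return "".join(
        c if rng.random() > rate else AAS[rng.integers(20)] for c in seq
    )


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(AAS[rng.integers(20)] for _ in range(n))


class TestAlign:
    def test_identical_sequences_no_gaps(self):
        msa = align_msa([
            ProteinRecord(id="a", sequence="ACDEFGHIK"),
            ProteinRecord(id="b", sequence="ACDEFGHIK"),
        ])
        assert msa.rows == ["ACDEFGHIK", "ACDEFGHIK"]

    def test_single_gap_example(self):
        ra, rb = pairwise_align("ACDE", "ACE")
        assert len(ra) == len(rb) == 4
        assert (ra + rb).count("-") == 1

    def test_all_rows_equal_length(self, rng):
        records = [
            ProteinRecord(id=f"s{i}", sequence=_random_seq(int(rng.integers(20, 60)), rng))
            for i in range(6)
        ]
        msa = align_msa(records)
        assert len({len(r) for r in msa.rows}) == 1
        assert set(msa.ids) == {r.id for r in records}
        # ungapping a row returns the input sequence
        by_id = {r.id: r.sequence for r in records}
        for seq_id, row in zip(msa.ids, msa.rows):
            assert row.replace("-", "") == by_id[seq_id]

    def test_pairwise_score_matches_bruteforce(self, rng):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        gap_open, gap_extend = 10.0, 0.2

        def score(x, y):
            return float(blosum[x, y])

        for _ in range(15):
            a = _random_seq(int(rng.integers(2, 7)), rng)
            b = _random_seq(int(rng.integers(2, 7)), rng)
            ra, rb = pairwise_align(a, b, gap_open=gap_open, gap_extend=gap_extend)
            got = 0.0
            state = 0
            for ca, cb in zip(ra, rb):
                if ca == "-" or cb == "-":
                    new_state = 1 if cb == "-" else 2
                    got += -(gap_extend if state == new_state else gap_open)
                    state = new_state
                else:
                    got += score(ca, cb)
                    state = 0
            best = global_alignment_bruteforce(a, b, score, gap_open, gap_extend)
            assert got == pytest.approx(best)

    def test_fewer_than_two_is_error(self):
        with pytest.raises(ValueError):
            align_msa([ProteinRecord(id="a", sequence="ACDE")])

    def test_extreme_length_excluded(self, rng, caplog):
        records = [
            ProteinRecord(id=f"s{i}", sequence=_random_seq(50, rng)) for i in range(4)
        ]
        records.append(ProteinRecord(id="huge", sequence=_random_seq(3000, rng)))
        with caplog.at_level("WARNING", logger="serscan.phylo"):
            msa = align_msa(records)
        assert "huge" not in msa.ids
        assert any("huge" in m for m in caplog.messages)


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = MSA(ids=["a", "b"], rows=["ACDEF", "ACDEF"])
        d = distance_matrix(msa)
        assert d.d[0, 1] == 0.0

    def test_p_distance_direct_count(self):
        msa = MSA(ids=["a", "b"], rows=["AAAAAAAAAA", "AAAAACCCCC"])
        assert distance_matrix(msa).d[0, 1] == 0.5

    def test_poisson_closed_form(self):
        msa = MSA(ids=["a", "b"], rows=["AAAAAAAAAA", "AAAAACCCCC"])
        d = distance_matrix(msa, model="poisson")
        assert d.d[0, 1] == pytest.approx(-math.log(0.5))

    def test_gap_columns_excluded(self):
        msa = MSA(ids=["a", "b"], rows=["AC-EF", "ACD-F"])  # 3 shared columns
        assert distance_matrix(msa).d[0, 1] == 0.0

    def test_no_shared_columns_error(self):
        msa = MSA(ids=["a", "b"], rows=["AC--", "--DE"])
        with pytest.raises(ValueError, match="a.*b"):
            distance_matrix(msa)

    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a", "b"], d=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNjTree:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(
            taxa=["a", "b", "c"],
            d=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = nj_tree(D)
        lengths = {c.label: l for c, l in tree.root.children}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_fewer_than_three_is_error(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=["a", "b"], d=np.zeros((2, 2))))

    def test_four_taxon_topology_recovery(self, rng):
        taxa, d, bips = random_additive_tree(4, rng)
        tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        assert tree.bipartitions() == bips

    def test_additive_recovery_100_trials(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            taxa, d, bips = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
            # Robinson-Foulds distance 0 <=> identical bipartition sets
            assert tree.bipartitions() == bips

    def test_input_order_invariance(self, rng):
        taxa, d, _ = random_additive_tree(7, rng)
        tree1 = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        perm = list(rng.permutation(len(taxa)))
        tree2 = nj_tree(
            DistanceMatrix(
                taxa=[taxa[i] for i in perm], d=d[np.ix_(perm, perm)]
            )
        )
        assert tree1.bipartitions() == tree2.bipartitions()

    def test_dendropy_agrees_on_rf_zero(self, rng):
        # cross-check the bipartition bookkeeping with an external library
        import dendropy

        taxa, d, _ = random_additive_tree(8, rng)
        tree = nj_tree(DistanceMatrix(taxa=taxa, d=d))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_csv(taxa, d), delimiter=","
        )
        ref = pdm.nj_tree()
        mine = dendropy.Tree.get(
            data=tree.newick(), schema="newick",
            taxon_namespace=ref.taxon_namespace, preserve_underscores=True,
        )
        ref.encode_bipartitions()
        mine.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(ref, mine)
        assert rf == 0


def _csv(taxa, d):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(taxa) + "\n")
    for i, t in enumerate(taxa):
        buf.write(t + "," + ",".join(f"{x:.10f}" for x in d[i]) + "\n")
    buf.seek(0)
    return buf


class TestBootstrap:
    def test_uniform_informative_columns_give_full_support(self):
        # 100 identical copies of one pattern: resampling cannot change it
        rows = {
            "a": "A", "b": "A", "c": "C", "d": "C", "e": "G",
        }
        msa = MSA(ids=list(rows), rows=[v * 100 for v in rows.values()])
        tree = bootstrap_supports(msa, n_replicates=50, seed=1)
        assert tree.supports  # has internal edges
        assert all(s == 100.0 for s in tree.supports.values())

    def test_planted_split_high_support(self, rng):
        base = _random_seq(80, rng)
        other = _mutate(base, 0.5, rng)
        ids, rows = [], []
        for i, anc in enumerate([base] * 4 + [other] * 4):
            ids.append(f"g{i}")
            rows.append(_mutate(anc, 0.02, rng))
        msa = MSA(ids=ids, rows=rows)
        tree = bootstrap_supports(msa, n_replicates=100, seed=2)
        split = frozenset(ids[:4])
        assert tree.support_of(split) >= 95.0

    def test_seed_determinism(self, rng):
        ids = [f"g{i}" for i in range(6)]
        rows = [_random_seq(60, rng) for _ in ids]
        msa = MSA(ids=ids, rows=rows)
        t1 = bootstrap_supports(msa, n_replicates=25, seed=7)
        t2 = bootstrap_supports(msa, n_replicates=25, seed=7)
        assert t1.supports == t2.supports

    def test_replicates_below_one_error(self):
        msa = MSA(ids=["a", "b", "c"], rows=["AC", "AC", "CC"])
        with pytest.raises(ValueError):
            bootstrap_supports(msa, n_replicates=0, seed=1)


def _subtype_dataset(rng, n_refs=4, n_cands=10, length=200,
                     within=0.06, subtypes="HLJ"):
    centroids = {s: _random_seq(length, rng) for s in subtypes}
    records, labels, truth = [], {}, {}
    for s in subtypes:
        for i in range(n_refs):
            rid = f"ref_{s}{i}"
            records.append(ProteinRecord(id=rid, sequence=_mutate(centroids[s], 0.04, rng)))
            labels[rid] = s
        for i in range(n_cands):
            rid = f"cand_{s}{i}"
            records.append(
                ProteinRecord(id=rid, sequence=_mutate(centroids[s], within, rng))
            )
            truth[rid] = s
    refs = ReferenceSet(
        records=[r for r in records if r.id.startswith("ref_")], labels=labels
    )
    return records, refs, truth


class TestAssignSubtypes:
    def test_candidate_inside_pure_reference_clade(self, rng):
        records, refs, truth = _subtype_dataset(rng, n_refs=3, n_cands=2, length=120)
        msa = align_msa(records)
        tree = bootstrap_supports(msa, n_replicates=50, seed=3)
        for call in assign_subtypes(tree, refs, min_support=40):
            assert call.subtype == truth[call.candidate_id]
            assert call.support is not None

    def test_reference_missing_from_tree_is_error(self, rng):
        records, refs, _ = _subtype_dataset(rng, n_refs=2, n_cands=1, length=80)
        msa = align_msa([r for r in records if r.id != "ref_H0"])
        tree = nj_tree(distance_matrix(msa))
        with pytest.raises(ValueError, match="ref_H0"):
            assign_subtypes(tree, refs)

    def test_mixed_clade_unclassified(self):
        # hand-built tree: candidate directly inside a two-subtype clade
        from serscan.phylo_classify import PhyloTree, _Node

        leaves = {name: _Node(label=name) for name in
                  ("cand", "refH", "refL", "refJ1", "refJ2")}
        inner = _Node(children=[(leaves["cand"], 1.0), (leaves["refH"], 1.0),
                                (leaves["refL"], 1.0)])
        root = _Node(children=[(inner, 1.0), (leaves["refJ1"], 1.0),
                               (leaves["refJ2"], 1.0)])
        tree = PhyloTree(root=root, taxa=list(leaves))
        recs = [ProteinRecord(id=n, sequence="ACDEF") for n in leaves if n != "cand"]
        refs = ReferenceSet(
            records=recs,
            labels={"refH": "H", "refL": "L", "refJ1": "J", "refJ2": "J"},
        )
        (call,) = [c for c in assign_subtypes(tree, refs) if c.candidate_id == "cand"]
        assert call.subtype == "unclassified"

    def test_starred_needs_support(self, rng):
        records, refs, truth = _subtype_dataset(rng, n_refs=3, n_cands=3)
        msa = align_msa(records)
        tree = bootstrap_supports(msa, n_replicates=20, seed=4)
        calls = assign_subtypes(tree, refs, min_support=40)
        for c in calls:
            if c.subtype.endswith("*"):
                assert c.support is not None and c.support >= 40

    def test_synthetic_60_candidates_accuracy(self, rng):
        records, refs, truth = _subtype_dataset(
            rng, n_refs=4, n_cands=20, length=200, within=0.08
        )
        msa = align_msa(records)
        tree = bootstrap_supports(msa, n_replicates=100, seed=5)
        calls = assign_subtypes(tree, refs, min_support=40)
        correct = sum(1 for c in calls if c.subtype == truth[c.candidate_id])
        assert correct / len(calls) >= 0.95
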