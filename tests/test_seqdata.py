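from __future__ import annotations

import numpy as np
import pytest

from serscan.seqdata import (
    CONDITIONS,
    ExpressionMatrix,
    FormatError,
    GeneLocus,
    ProteinRecord,
    ReferenceSet,
    read_expression,
    read_fasta,
    read_loci,
    write_expression,
    write_fasta,
    write_loci,
)

from conftest import random_protein


class TestProteinRecord:
    def test_rejects_empty_sequence(self):
        with pytest.raises(ValueError):
            ProteinRecord(id="a", sequence="")

    def test_rejects_invalid_residue(self):
        with pytest.raises(ValueError):
            ProteinRecord(id="a", sequence="ACDEF*")

    def test_length(self):
        assert len(ProteinRecord(id="a", sequence="ACDEF")) == 5


class TestGeneLocus:
    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            GeneLocus("scf1", 200, 100, "g", "+")

    def test_rejects_bad_strand(self):
        with pytest.raises(ValueError):
            GeneLocus("scf1", 0, 10, "g", ".")


class TestReadFasta:
    def test_case_normalization(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacdef\n")
        records = read_fasta(p)
        assert records == [ProteinRecord(id="a", sequence="ACDEF")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_strips_stops_and_gaps_with_warning(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nAC-DE*F\n")
        with pytest.warns(UserWarning):
            records = read_fasta(p)
        assert records[0].sequence == "ACDEF"

    def test_nonstandard_residue_maps_to_x(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACDEBF\n")
        with pytest.warns(UserWarning, match="non-standard"):
            records = read_fasta(p)
        assert records[0].sequence == "ACDEXF"

    def test_empty_sequence_is_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\n>b\nACDEF\n")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACDEF\n>\nACDEF\n")
        with pytest.raises(FormatError, match="line 3"):
            read_fasta(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACDEF\n>a\nACDEF\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_round_trip_50_random_records(self, tmp_path, rng):
        records = [
            random_protein(rng, int(rng.integers(1, 400)), protein_id=f"p{i}")
            for i in range(50)
        ]
        path = tmp_path / "round.fasta"
        write_fasta(records, path)
        assert read_fasta(path) == records


class TestReadLoci:
    def test_gff3_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "scf1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        )
        (locus,) = read_loci(p)
        assert (locus.start, locus.end) == (100, 200)

    def test_bed_is_half_open_already(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("scf1\t100\t200\tg1\t0\t+\n")
        (locus,) = read_loci(p)
        assert (locus.start, locus.end) == (100, 200)

    def test_sorted_by_scaffold_then_start(self, tmp_path, rng):
        rows = []
        expected = []
        for i in range(40):
            scf = f"scf{int(rng.integers(1, 5))}"
            start = int(rng.integers(0, 10_000))
            end = start + int(rng.integers(1, 500))
            rows.append(f"{scf}\t{start}\t{end}\tg{i}\t0\t+")
            expected.append((scf, start))
        p = tmp_path / "mixed.bed"
        p.write_text("\n".join(rows) + "\n")
        loci = read_loci(p)
        assert [(l.scaffold_id, l.start) for l in loci] == sorted(expected)

    def test_end_before_start_is_error(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("scf1\t200\t100\tg1\n")
        with pytest.raises(FormatError):
            read_loci(p)

    def test_gff3_skips_non_gene_features(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "scf1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "scf1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=m1\n"
        )
        assert [l.gene_id for l in read_loci(p)] == ["g1"]

    def test_round_trip_gff3_and_bed(self, tmp_path, rng):
        loci = []
        pos = 0
        for i in range(30):
            start = pos + int(rng.integers(1, 100))
            end = start + int(rng.integers(1, 300))
            pos = end
            loci.append(GeneLocus("scf1", start, end, f"g{i}",
                                  "+" if rng.random() < 0.5 else "-"))
        for fmt in ("gff3", "bed"):
            path = tmp_path / f"r.{fmt}"
            write_loci(loci, path, fmt=fmt)
            assert read_loci(path, fmt) == sorted(
                loci, key=lambda l: (l.scaffold_id, l.start, l.end, l.gene_id)
            )


def _expr_frame_text(gene_rows: dict[str, list[float]], columns=CONDITIONS) -> str:
    header = "gene_id\t" + "\t".join(columns)
    lines = [header]
    for g, vals in gene_rows.items():
        lines.append(g + "\t" + "\t".join(str(v) for v in vals))
    return "\n".join(lines) + "\n"


class TestReadExpression:
    def test_canonical_order(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text(_expr_frame_text({"g1": list(range(20)), "g2": list(range(20))}))
        m = read_expression(p)
        assert m.values.shape == (2, 20)
        assert m.condition_ids == list(CONDITIONS)

    def test_shuffled_columns_reordered(self, tmp_path, rng):
        perm = list(rng.permutation(20))
        cols = [CONDITIONS[i] for i in perm]
        vals = [float(v) for v in rng.normal(size=20)]
        p = tmp_path / "e.tsv"
        p.write_text(_expr_frame_text({"g1": vals}, columns=cols))
        m = read_expression(p)
        expected = [vals[perm.index(i)] for i in range(20)]
        np.testing.assert_allclose(m.values[0], expected)

    def test_unknown_condition_label(self, tmp_path):
        cols = list(CONDITIONS[:19]) + ["BOGUS"]
        p = tmp_path / "e.tsv"
        p.write_text(_expr_frame_text({"g1": list(range(20))}, columns=cols))
        with pytest.raises(FormatError, match="BOGUS"):
            read_expression(p)

    def test_duplicate_gene_id(self, tmp_path):
        text = _expr_frame_text({"g1": list(range(20))})
        text += "g1\t" + "\t".join(["0"] * 20) + "\n"
        p = tmp_path / "e.tsv"
        p.write_text(text)
        with pytest.raises(FormatError, match="duplicate"):
            read_expression(p)

    def test_missing_value_rejected_then_imputed(self, tmp_path):
        vals = [str(v) for v in range(20)]
        vals[3] = ""
        p = tmp_path / "e.tsv"
        p.write_text(
            "gene_id\t" + "\t".join(CONDITIONS) + "\ng1\t" + "\t".join(vals) + "\n"
        )
        with pytest.raises(FormatError):
            read_expression(p)
        m = read_expression(p, impute_median=True)
        row = [float(v) for i, v in enumerate(range(20)) if i != 3]
        assert m.values[0, 3] == np.median(row)

    def test_round_trip_full_precision(self, tmp_path, rng):
        values = rng.normal(size=(17, 20))
        m = ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(17)],
            condition_ids=list(CONDITIONS),
            values=values,
        )
        path = tmp_path / "round.tsv"
        write_expression(m, path)
        m2 = read_expression(path)
        assert m2.gene_ids == m.gene_ids
        np.testing.assert_array_equal(m2.values, m.values)


class TestReferenceSet:
    def test_label_for_missing_record_rejected(self):
        rec = ProteinRecord(id="a", sequence="ACDEF")
        with pytest.raises(ValueError):
            ReferenceSet(records=[rec], labels={"b": "H"})

    def test_members(self):
        recs = [ProteinRecord(id=i, sequence="ACDEF") for i in ("a", "b", "c")]
        rs = ReferenceSet(records=recs, labels={"a": "H", "b": "H", "c": "L"})
        assert rs.subtypes == {"H", "L"}
        assert sorted(rs.members("H")) == ["a", "b"]
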