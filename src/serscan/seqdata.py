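"""Domain types and readers/writers for the external file formats.

All coordinates are 0-based half-open internally.  GFF3 input (1-based,
inclusive) is converted on ingest; BED is taken as-is.  No science lives
here — only parsing, validation and deterministic serialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "CONDITIONS",
    "FormatError",
    "ProteinRecord",
    "GeneLocus",
    "ExpressionMatrix",
    "ReferenceSet",
    "read_fasta",
    "write_fasta",
    "read_loci",
    "write_loci",
    "read_expression",
    "write_expression",
    "read_reference_set",
]

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Internal alphabet: standard residues plus X for anything ambiguous.
ALPHABET = AMINO_ACIDS + "X"

#: Canonical expression condition labels, in canonical column order:
#: three growth densities, seven starvation and ten conjugation time points.
CONDITIONS = (
    "Ll", "Lm", "Lh",
    "S0", "S3", "S6", "S9", "S12", "S15", "S24",
    "C0", "C2", "C4", "C6", "C8", "C10", "C12", "C14", "C16", "C18",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single identified amino-acid sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"protein record {self.id!r} contains invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GeneLocus:
    """A gene interval on a scaffold, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"locus {self.gene_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.gene_id!r}: strand must be '+' or '-'")


@dataclass
class ExpressionMatrix:
    """A genes x conditions matrix of log2 expression values."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.condition_ids
        )


@dataclass
class ReferenceSet:
    """Reference proteins with known subtype labels."""

    records: list[ProteinRecord]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        missing = set(self.labels) - ids
        if missing:
            raise ValueError(f"labels refer to absent records: {sorted(missing)}")
        if not self.labels:
            raise ValueError("reference set has no labelled records")

    @property
    def subtypes(self) -> set[str]:
        return set(self.labels.values())

    def members(self, subtype: str) -> list[str]:
        return [g for g, s in self.labels.items() if s == subtype]


# ---------------------------------------------------------------------------
# FASTA


def _clean_sequence(raw: str, rec_id: str, line_no: int) -> str:
    seq = raw.upper()
    if "*" in seq or "-" in seq:
        warnings.warn(
            f"record {rec_id!r}: stripping gap/stop characters from sequence",
            stacklevel=3,
        )
        seq = seq.replace("*", "").replace("-", "")
    nonstd = set(seq) - set(ALPHABET)
    if nonstd:
        warnings.warn(
            f"record {rec_id!r}: mapping non-standard residues "
            f"{sorted(nonstd)} to X",
            stacklevel=3,
        )
        seq = "".join(c if c in ALPHABET else "X" for c in seq)
    if not seq:
        raise FormatError(f"empty sequence for record {rec_id!r} near line {line_no}")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased; gap (``-``) and stop (``*``) characters are
    stripped with a warning; residues outside the 21-letter alphabet are
    mapped to ``X`` with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    rec_id: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal rec_id
        if rec_id is None:
            return
        seq = _clean_sequence("".join(chunks), rec_id, line_no)
        if rec_id in seen:
            raise FormatError(f"duplicate record id {rec_id!r} near line {line_no}")
        seen.add(rec_id)
        records.append(ProteinRecord(id=rec_id, sequence=seq, description=desc))
        rec_id = None
        chunks.clear()

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(line_no - 1)
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"malformed FASTA header at line {line_no}")
                parts = header.split(None, 1)
                rec_id = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                header_line = line_no
                chunks = []
            else:
                if rec_id is None:
                    raise FormatError(
                        f"sequence data before any header at line {line_no}"
                    )
                if any(c.isspace() for c in line.strip()):
                    raise FormatError(f"whitespace inside sequence at line {line_no}")
                chunks.append(line.strip())
        flush(header_line + 1)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping (deterministic)."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene loci (GFF3 / BED)


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            key, _, value = item.partition("=")
            out[key.strip()] = value.strip()
    return out


def read_loci(path: str | Path, fmt: str | None = None) -> list[GeneLocus]:
    """Read gene loci from a GFF3 (gene features) or BED file.

    GFF3 coordinates (1-based, inclusive) are converted to 0-based
    half-open.  Output is sorted by (scaffold, start).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "bed"
    fmt = fmt.lower()
    if fmt not in ("gff3", "gff", "bed"):
        raise ValueError(f"unknown loci format {fmt!r}")

    loci: list[GeneLocus] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt in ("gff3", "gff"):
                if len(fields) < 9:
                    raise FormatError(f"GFF3 line {line_no}: expected 9 columns")
                if fields[2] != "gene":
                    continue
                scaffold, start1, end1, strand = (
                    fields[0], fields[3], fields[4], fields[6],
                )
                attrs = _parse_gff3_attributes(fields[8])
                gene_id = attrs.get("ID") or attrs.get("Name")
                if not gene_id:
                    raise FormatError(f"GFF3 line {line_no}: gene without ID attribute")
                start, end = int(start1) - 1, int(end1)
            else:
                if len(fields) < 3:
                    raise FormatError(f"BED line {line_no}: expected >= 3 columns")
                scaffold, start, end = fields[0], int(fields[1]), int(fields[2])
                gene_id = fields[3] if len(fields) > 3 else f"{scaffold}:{start}-{end}"
                strand = fields[5] if len(fields) > 5 else "+"
            if end <= start:
                raise FormatError(
                    f"{fmt.upper()} line {line_no}: end ({end}) <= start ({start})"
                )
            try:
                loci.append(
                    GeneLocus(
                        scaffold_id=scaffold, start=start, end=end,
                        gene_id=gene_id, strand=strand,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{fmt.upper()} line {line_no}: {exc}") from exc
    loci.sort(key=lambda l: (l.scaffold_id, l.start, l.end, l.gene_id))
    return loci


def write_loci(loci: Iterable[GeneLocus], path: str | Path, fmt: str = "gff3") -> None:
    """Write loci as GFF3 gene features or BED6, sorted deterministically."""
    loci = sorted(loci, key=lambda l: (l.scaffold_id, l.start, l.end, l.gene_id))
    fmt = fmt.lower()
    with open(path, "w", newline="\n") as fh:
        if fmt in ("gff3", "gff"):
            fh.write("##gff-version 3\n")
            for l in loci:
                fh.write(
                    f"{l.scaffold_id}\tserscan\tgene\t{l.start + 1}\t{l.end}\t.\t"
                    f"{l.strand}\t.\tID={l.gene_id}\n"
                )
        elif fmt == "bed":
            for l in loci:
                fh.write(
                    f"{l.scaffold_id}\t{l.start}\t{l.end}\t{l.gene_id}\t0\t{l.strand}\n"
                )
        else:
            raise ValueError(f"unknown loci format {fmt!r}")


# ---------------------------------------------------------------------------
# Expression matrix (TSV)


def read_expression(path: str | Path, impute_median: bool = False) -> ExpressionMatrix:
    """Read a TSV expression table (first column gene id, 20 condition columns).

    Columns are reordered into canonical condition order.  Missing values
    are rejected unless ``impute_median`` is set, in which case each gap is
    filled with its row median.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in CONDITIONS]
    if unknown:
        raise FormatError(f"unknown condition labels: {unknown}")
    missing = [c for c in CONDITIONS if c not in df.columns]
    if missing:
        raise FormatError(f"missing condition columns: {missing}")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"duplicate gene ids: {dups}")
    df = df[list(CONDITIONS)]
    if df.isna().any().any():
        if not impute_median:
            bad = sorted(df.index[df.isna().any(axis=1)])
            raise FormatError(f"missing expression values for genes: {bad}")
        med = df.median(axis=1)
        df = df.apply(lambda col: col.fillna(med))
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        condition_ids=list(CONDITIONS),
        values=df.to_numpy(dtype=float),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV with full float precision."""
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g", lineterminator="\n")


def read_reference_set(
    fasta_path: str | Path, labels: str | Path | Mapping[str, str]
) -> ReferenceSet:
    """Load reference proteins plus a gene_id -> subtype label table.

    ``labels`` may be a mapping or a path to a two-column TSV
    (gene_id, subtype).
    """
    records = read_fasta(fasta_path)
    if isinstance(labels, (str, Path)):
        table = pd.read_csv(labels, sep="\t", header=None, names=["gene_id", "subtype"],
                            dtype=str, comment="#")
        label_map = dict(zip(table["gene_id"], table["subtype"]))
    else:
        label_map = dict(labels)
    return ReferenceSet(records=records, labels=label_map)
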