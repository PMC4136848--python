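"""Synthetic proteomes, scaffold layouts and expression matrices with truth.

Every generator is deterministic under an explicit seed (or an injected
``numpy`` Generator) and returns machine-readable ground truth alongside
the data, so recall/precision, repeat decomposition, subtype assignment
and clustering can all be scored without external downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .gpi_signal import GpiParams, score_gpi_signal
from .motif_scan import CysPatternParams, find_cys_blocks
from .seqdata import (
    AMINO_ACIDS,
    CONDITIONS,
    ExpressionMatrix,
    GeneLocus,
    ProteinRecord,
)

__all__ = [
    "SubtypeSpec",
    "ProteomeConfig",
    "GenomeLayoutConfig",
    "ExpressionConfig",
    "generate_ser_protein",
    "generate_proteome",
    "generate_genome_layout",
    "generate_expression",
    "write_truth",
]

#: 19 background residues (no cysteine).
_BACKGROUND = AMINO_ACIDS.replace("C", "")
#: spacer residues: all have negative Kyte-Doolittle hydropathy
_POLAR = "NDQEST"
#: hydrophobic-tail residues: strongly positive hydropathy
_HYDROPHOBIC = "LIVFM"
#: small residues accepted at the attachment (omega) site
_OMEGA = "GASN"


@dataclass(frozen=True)
class SubtypeSpec:
    """Blueprint of one planted subtype's repeat architecture."""

    name: str
    cys_per_block: int
    block_len_range: tuple[int, int] = (55, 100)
    n_blocks_range: tuple[int, int] = (3, 8)

    def __post_init__(self) -> None:
        if self.cys_per_block not in (6, 8, 10):
            raise ValueError("cys_per_block must be 6, 8 or 10")
        lo, hi = self.block_len_range
        min_span = 6 + (self.cys_per_block - 2) + self.cys_per_block
        if lo > hi or lo < min_span:
            raise ValueError(
                f"block length range {self.block_len_range} cannot hold "
                f"{self.cys_per_block} cysteines (needs >= {min_span})"
            )
        if self.n_blocks_range[0] < 2 or self.n_blocks_range[0] > self.n_blocks_range[1]:
            raise ValueError("invalid n_blocks_range")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _residues(rng: np.random.Generator, n: int, cys_rate: float = 0.0) -> str:
    picks = rng.choice(list(_BACKGROUND), size=n)
    if cys_rate > 0:
        mask = rng.random(n) < cys_rate
        picks[mask] = "C"
    return "".join(picks)


def _cys_offsets(rng: np.random.Generator, cys_count: int, block_len: int) -> list[int]:
    """Cysteine offsets within one block; the first six satisfy the motif."""
    limit = min(120, block_len)
    for _ in range(100):
        gaps = [int(rng.integers(6, 12))] + [
            int(rng.integers(1, 4)) for _ in range(cys_count - 2)
        ]
        offsets = [0]
        for g in gaps:
            offsets.append(offsets[-1] + g + 1)
        if offsets[-1] < limit:
            return offsets
    # fall back to the tightest layout
    gaps = [6] + [1] * (cys_count - 2)
    offsets = [0]
    for g in gaps:
        offsets.append(offsets[-1] + g + 1)
    if offsets[-1] >= limit:
        raise ValueError(
            f"block of {block_len} aa cannot hold {cys_count} cysteines"
        )
    return offsets


def _block(rng: np.random.Generator, offsets: Sequence[int], block_len: int) -> str:
    chars = list(_residues(rng, block_len))
    for o in offsets:
        chars[o] = "C"
    # keep filler cysteine-free so the planted pattern is the only one
    return "".join(chars)


def _gpi_signal(rng: np.random.Generator) -> str:
    omega = str(rng.choice(list(_OMEGA)))
    linker = _residues(rng, 2)
    spacer = "".join(rng.choice(list(_POLAR), size=6))
    tail_len = int(rng.integers(10, 15))
    tail = "".join(rng.choice(list(_HYDROPHOBIC), size=tail_len))
    return omega + linker + spacer + tail


def generate_ser_protein(
    spec: SubtypeSpec, rng, protein_id: str = "ser_0"
) -> tuple[ProteinRecord, dict]:
    """One planted repeat protein: periodic cysteine blocks + anchor signal.

    All blocks share one cysteine layout (hence one exact period); filler
    residues are random and cysteine-free; a compliant GPI signal is
    appended.
    """
    rng = _rng(rng)
    block_len = int(rng.integers(spec.block_len_range[0], spec.block_len_range[1] + 1))
    n_blocks = int(rng.integers(spec.n_blocks_range[0], spec.n_blocks_range[1] + 1))
    offsets = _cys_offsets(rng, spec.cys_per_block, block_len)
    blocks = [_block(rng, offsets, block_len) for _ in range(n_blocks)]
    seq = "".join(blocks) + _gpi_signal(rng)
    record = ProteinRecord(id=protein_id, sequence=seq)
    truth = {
        "class": "ser",
        "subtype": spec.name,
        "period": block_len,
        "n_blocks": n_blocks,
        "cys_per_block": spec.cys_per_block,
    }
    return record, truth


@dataclass(frozen=True)
class ProteomeConfig:
    """Counts per fixture class for a mixed synthetic proteome."""

    n_ser: int = 200
    n_decoy_no_gpi: int = 200
    n_decoy_no_pattern: int = 200
    n_background: int = 400
    subtype_specs: tuple[SubtypeSpec, ...] = (
        SubtypeSpec("L", 6),
        SubtypeSpec("H", 8),
        SubtypeSpec("J", 10),
    )
    background_cys_rate: float = 0.02
    background_len_range: tuple[int, int] = (150, 600)


def _acidify_tail(seq: str, rng: np.random.Generator) -> str:
    """Replace the hydrophobic tail with acidic residues, length preserved."""
    tail_len = len(seq) - len(seq.rstrip(_HYDROPHOBIC))
    acid = "".join(rng.choice(list("DE"), size=tail_len))
    return seq[: len(seq) - tail_len] + acid


def generate_proteome(
    config: ProteomeConfig, seed: int
) -> tuple[list[ProteinRecord], dict[str, dict]]:
    """Mixed proteome of planted proteins, decoys and background.

    Class guarantees (enforced by construction and rejection sampling):
    ``ser`` passes both filters; ``decoy_no_gpi`` passes the pattern but
    not the GPI gate; ``decoy_no_pattern`` passes the GPI gate but has no
    motif; ``background`` never passes both.
    """
    rng = _rng(seed)
    gpi_params = GpiParams()
    scan_params = CysPatternParams()
    records: list[ProteinRecord] = []
    truth: dict[str, dict] = {}

    def add(record: ProteinRecord, info: dict) -> None:
        records.append(record)
        truth[record.id] = info

    specs = config.subtype_specs
    for i in range(config.n_ser):
        spec = specs[i % len(specs)]
        rec, info = generate_ser_protein(spec, rng, protein_id=f"ser_{i:04d}")
        add(rec, info)

    for i in range(config.n_decoy_no_gpi):
        spec = specs[i % len(specs)]
        for _ in range(50):
            rec, _ = generate_ser_protein(spec, rng, protein_id=f"dng_{i:04d}")
            seq = _acidify_tail(rec.sequence, rng)
            rec = ProteinRecord(id=rec.id, sequence=seq)
            if score_gpi_signal(rec, gpi_params).gpi_class != "highly_probable":
                break
        else:  # pragma: no cover - rejection virtually never exhausts
            raise RuntimeError("failed to build a no-GPI decoy")
        add(rec, {"class": "decoy_no_gpi", "subtype": None})

    for i in range(config.n_decoy_no_pattern):
        body = _residues(rng, int(rng.integers(*config.background_len_range)))
        seq = body + _gpi_signal(rng)
        rec = ProteinRecord(id=f"dnp_{i:04d}", sequence=seq)
        add(rec, {"class": "decoy_no_pattern", "subtype": None})

    for i in range(config.n_background):
        for _ in range(50):
            n = int(rng.integers(*config.background_len_range))
            rec = ProteinRecord(
                id=f"bg_{i:04d}",
                sequence=_residues(rng, n, cys_rate=config.background_cys_rate),
            )
            if not find_cys_blocks(rec, scan_params):
                break
            if score_gpi_signal(rec, gpi_params).gpi_class != "highly_probable":
                break
        else:  # pragma: no cover
            raise RuntimeError("failed to build a background protein")
        add(rec, {"class": "background", "subtype": None})

    return records, truth


@dataclass(frozen=True)
class GenomeLayoutConfig:
    """Shape of the synthetic scaffold layout."""

    n_scaffolds: int = 6
    arrays_per_scaffold: int = 1
    array_size_range: tuple[int, int] = (3, 6)
    n_singletons: int = 4
    n_filler_per_scaffold: int = 12
    intervening_rate: float = 0.0  # chance of one non-candidate inside an array
    antisense_rate: float = 0.0  # chance a member sits on the minus strand
    subtypes: tuple[str, ...] = ("L", "H", "J")
    gene_len_range: tuple[int, int] = (900, 2400)
    gap_range: tuple[int, int] = (300, 1500)


def generate_genome_layout(
    config: GenomeLayoutConfig,
    seed: int,
    candidate_ids: Sequence[str] | None = None,
    subtypes_by_id: dict[str, str] | None = None,
) -> tuple[list[GeneLocus], dict]:
    """Scaffolds carrying same-subtype tandem arrays plus filler genes.

    Candidate gene ids are minted as ``cand_NNNN`` unless ``candidate_ids``
    supplies a pool (e.g. planted proteome ids) to consume in order; member
    subtypes then follow ``subtypes_by_id`` where available.  Returns all
    loci (candidates and filler, disjoint intervals) and truth: planted
    arrays (ordered member ids, subtype), singleton candidate ids and a
    candidate id -> subtype map.
    """
    rng = _rng(seed)
    loci: list[GeneLocus] = []
    arrays_truth: list[dict] = []
    subtype_of: dict[str, str] = {}
    singletons: list[str] = []
    pool = list(candidate_ids) if candidate_ids else []
    pool_pos = 0
    cand_counter = 0
    filler_counter = 0

    def next_candidate_id() -> str:
        nonlocal pool_pos, cand_counter
        if pool_pos < len(pool):
            gene_id = pool[pool_pos]
            pool_pos += 1
        else:
            gene_id = f"cand_{cand_counter:04d}"
            cand_counter += 1
        return gene_id

    def next_span(pos: int) -> tuple[int, int]:
        start = pos + int(rng.integers(*config.gap_range))
        end = start + int(rng.integers(*config.gene_len_range))
        return start, end

    for s in range(config.n_scaffolds):
        scaffold = f"scf_{s + 1}"
        pos = 0

        def place(gene_id: str, strand: str) -> None:
            nonlocal pos
            start, end = next_span(pos)
            loci.append(GeneLocus(scaffold, start, end, gene_id, strand))
            pos = end

        def place_filler(n: int) -> None:
            nonlocal filler_counter
            for _ in range(n):
                place(f"filler_{filler_counter:04d}", "+")
                filler_counter += 1

        place_filler(2)
        for _ in range(config.arrays_per_scaffold):
            size = int(
                rng.integers(config.array_size_range[0], config.array_size_range[1] + 1)
            )
            subtype = str(rng.choice(list(config.subtypes)))
            members: list[str] = []
            for m in range(size):
                gene_id = next_candidate_id()
                strand = "-" if rng.random() < config.antisense_rate else "+"
                place(gene_id, strand)
                members.append(gene_id)
                subtype_of[gene_id] = (subtypes_by_id or {}).get(gene_id, subtype)
                if m < size - 1 and rng.random() < config.intervening_rate:
                    place_filler(1)
            arrays_truth.append(
                {"scaffold_id": scaffold, "member_ids": members, "subtype": subtype}
            )
            # >= 2 fillers guarantee array separation at max_intervening = 1
            place_filler(3)
        place_filler(config.n_filler_per_scaffold)

    # singletons scattered on their own scaffolds, isolated by fillers
    for i in range(config.n_singletons):
        scaffold = f"scf_single_{i + 1}"
        pos = 0
        start, end = pos + 400, pos + 1600
        loci.append(GeneLocus(scaffold, start, end, f"filler_{filler_counter:04d}", "+"))
        filler_counter += 1
        gene_id = next_candidate_id()
        subtype = str(rng.choice(list(config.subtypes)))
        subtype_of[gene_id] = (subtypes_by_id or {}).get(gene_id, subtype)
        singletons.append(gene_id)
        loci.append(GeneLocus(scaffold, end + 500, end + 2000, gene_id, "+"))

    loci.sort(key=lambda l: (l.scaffold_id, l.start))
    truth = {
        "arrays": arrays_truth,
        "singletons": singletons,
        "subtype_of": subtype_of,
    }
    return loci, truth


@dataclass(frozen=True)
class ExpressionConfig:
    """Planted cluster structure for a synthetic expression matrix."""

    k: int = 5
    genes_per_cluster: int = 20
    noise_sd: float = 0.5
    amplitude: float = 2.0
    baseline: float = 8.0
    arrays: tuple[tuple[str, ...], ...] = ()  # optional tandem-array members
    p_same_cluster: float = 1.0  # chance an array shares one true cluster


def _simplex_centroids(k: int, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """k mutually anti-correlated shapes (pairwise correlation ~ -1/(k-1))."""
    n_cond = len(CONDITIONS)
    # random orthonormal directions, then subtract their mean: a simplex
    raw = rng.standard_normal((k, n_cond))
    q, _ = np.linalg.qr(raw.T)
    u = q[:, :k].T
    w = u - u.mean(axis=0, keepdims=True)
    w = w - w.mean(axis=1, keepdims=True)  # center over conditions
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return amplitude * np.sqrt(n_cond) * w


def generate_expression(
    config: ExpressionConfig, seed: int
) -> tuple[ExpressionMatrix, dict]:
    """Complete 20-condition matrix with planted cluster labels.

    Array members (if configured) share one true cluster with probability
    ``p_same_cluster``; remaining genes fill the clusters evenly.
    """
    rng = _rng(seed)
    centroids = _simplex_centroids(config.k, rng, config.amplitude)

    gene_ids: list[str] = []
    labels: dict[str, int] = {}

    for members in config.arrays:
        if rng.random() < config.p_same_cluster:
            cluster = int(rng.integers(config.k)) + 1
            for m in members:
                labels[m] = cluster
        else:
            for m in members:
                labels[m] = int(rng.integers(config.k)) + 1
        gene_ids.extend(members)

    n_extra = config.k * config.genes_per_cluster
    for i in range(n_extra):
        gene_id = f"gene_{i:04d}"
        gene_ids.append(gene_id)
        labels[gene_id] = (i % config.k) + 1

    values = np.empty((len(gene_ids), len(CONDITIONS)))
    for row, g in enumerate(gene_ids):
        c = centroids[labels[g] - 1]
        values[row] = (
            config.baseline + c + rng.normal(0.0, config.noise_sd, size=len(CONDITIONS))
        )
    matrix = ExpressionMatrix(
        gene_ids=gene_ids, condition_ids=list(CONDITIONS), values=values
    )
    return matrix, {"cluster_of": labels, "k": config.k}


def write_truth(truth: dict, path: str | Path) -> None:
    """Serialize a truth mapping as pretty JSON (deterministic key order)."""
    with open(path, "w", newline="\n") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
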