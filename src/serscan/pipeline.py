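"""End-to-end orchestration: scan -> GPI gate -> blocks -> classify ->
tandem arrays -> expression clusters.

Downstream stages run only when their inputs are configured; every output
file is written with a deterministic row order so a rerun under the same
config and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .expression_cluster import (
    ClusterParams,
    cluster_array_concordance,
    kmeans_pearson,
)
from .genome_context import detect_tandem_arrays, tandem_summary
from .gpi_signal import GpiParams, filter_candidates, score_gpi_signal
from .motif_scan import CysPatternParams, screen_proteome
from .phylo_classify import MSA, align_msa, assign_subtypes, bootstrap_supports
from .repeat_blocks import decompose_repeats
from .seqdata import (
    read_expression,
    read_fasta,
    read_loci,
    read_reference_set,
)

__all__ = ["PipelineConfig", "run_pipeline", "read_msa", "write_msa"]


def read_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA (gaps preserved) into an MSA."""
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                ids.append(line[1:].split()[0])
                current = []
                rows.append(current)  # type: ignore[arg-type]
            elif current is not None:
                current.append(line.upper())
    return MSA(ids=ids, rows=["".join(r) for r in rows])


def write_msa(msa: MSA, path: str | Path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for seq_id, row in zip(msa.ids, msa.rows):
            fh.write(f">{seq_id}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters for a full run."""

    fasta: Path
    outdir: Path
    loci: Path | None = None
    loci_format: str | None = None
    expression: Path | None = None
    reference_fasta: Path | None = None
    reference_labels: Path | None = None
    msa: Path | None = None
    seed: int = 0
    scan_params: CysPatternParams = field(default_factory=CysPatternParams)
    gpi_params: GpiParams = field(default_factory=GpiParams)
    min_blocks: int = 2
    block_tolerance: float = 0.25
    bootstrap_replicates: int = 100
    min_support: float = 40.0
    distance_model: str = "p"
    max_intervening: int = 1
    cluster_params: ClusterParams = field(default_factory=lambda: ClusterParams())
    skip_stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        self.outdir = Path(self.outdir)
        for name in ("loci", "expression", "reference_fasta",
                     "reference_labels", "msa"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        required = [self.fasta] + [
            p for p in (self.loci, self.expression, self.reference_fasta,
                        self.reference_labels, self.msa)
            if p is not None
        ]
        missing = [str(p) for p in required if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        scan = CysPatternParams(**raw.pop("scan", {}))
        gpi_kwargs = raw.pop("gpi", {})
        if "omega_residues" in gpi_kwargs:
            gpi_kwargs["omega_residues"] = frozenset(gpi_kwargs["omega_residues"])
        if "omega_search_window" in gpi_kwargs:
            gpi_kwargs["omega_search_window"] = tuple(gpi_kwargs["omega_search_window"])
        gpi = GpiParams(**gpi_kwargs)
        cluster = ClusterParams(**raw.pop("cluster", {}))
        if "skip_stages" in raw:
            raw["skip_stages"] = tuple(raw["skip_stages"])
        return cls(scan_params=scan, gpi_params=gpi, cluster_params=cluster, **raw)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run report."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "scan": {
                "n_cys": config.scan_params.n_cys,
                "min_first_gap": config.scan_params.min_first_gap,
                "min_inner_gap": config.scan_params.min_inner_gap,
                "max_inner_gap": config.scan_params.max_inner_gap,
                "window_min": config.scan_params.window_min,
                "window_max": config.scan_params.window_max,
            },
            "gpi": {
                "omega_residues": "".join(sorted(config.gpi_params.omega_residues)),
                "omega_search_window": list(config.gpi_params.omega_search_window),
                "min_polar_spacer": config.gpi_params.min_polar_spacer,
                "min_tail_len": config.gpi_params.min_tail_len,
                "min_tail_hydropathy": config.gpi_params.min_tail_hydropathy,
            },
            "min_support": config.min_support,
            "bootstrap_replicates": config.bootstrap_replicates,
            "max_intervening": config.max_intervening,
            "cluster_k": config.cluster_params.k,
        },
        "stages": {},
    }

    # --- stage 1: pattern scan -------------------------------------------
    records = read_fasta(config.fasta)
    screen = screen_proteome(records, config.scan_params)
    scan_rows = []
    for rec in records:
        for m in screen.matches[rec.id]:
            scan_rows.append(
                [rec.id, m.anchor, ",".join(map(str, m.cys_positions)), m.span]
            )
    _write_tsv(outdir / "scan.tsv",
               ["protein_id", "anchor", "cys_positions", "span"], scan_rows)
    report["stages"]["scan"] = {
        "n_proteins": len(records),
        "n_pattern_hits": screen.n_hits,
    }

    # --- stage 2: GPI gate ------------------------------------------------
    by_id = {r.id: r for r in records}
    hits = [by_id[i] for i in screen.hit_ids]
    candidates = filter_candidates(hits, config.gpi_params)
    gpi_rows = []
    for rec in hits:
        sig = score_gpi_signal(rec, config.gpi_params)
        gpi_rows.append([
            rec.id,
            sig.omega_index if sig.omega_index is not None else "NA",
            sig.tail_len,
            f"{sig.tail_hydropathy:.4f}",
            f"{sig.score:.4f}",
            sig.gpi_class,
        ])
    _write_tsv(outdir / "gpi.tsv",
               ["protein_id", "omega_index", "tail_len", "tail_kd", "score", "class"],
               gpi_rows)
    candidate_ids = [r.id for r in candidates]
    report["stages"]["gpi"] = {"n_candidates": len(candidates)}

    # --- stage 3: repeat blocks ------------------------------------------
    if "blocks" not in config.skip_stages:
        block_rows = []
        for rec in candidates:
            dec = decompose_repeats(
                rec, screen.matches[rec.id],
                min_blocks=config.min_blocks, tolerance=config.block_tolerance,
            )
            block_rows.append([
                rec.id, dec.period, dec.n_blocks,
                dec.modal_cys_per_block if dec.modal_cys_per_block is not None else "NA",
                dec.block_length_range[0], dec.block_length_range[1],
            ])
        _write_tsv(
            outdir / "blocks.tsv",
            ["protein_id", "period", "n_blocks", "modal_cys_per_block",
             "min_len", "max_len"],
            block_rows,
        )
        report["stages"]["blocks"] = {"n_decomposed": len(block_rows)}

    # --- stage 4: phylogenetic classification ----------------------------
    assignments_map: dict[str, str] = {}
    if (
        config.reference_fasta is not None
        and config.reference_labels is not None
        and "classify" not in config.skip_stages
    ):
        refs = read_reference_set(config.reference_fasta, config.reference_labels)
        if config.msa is not None:
            msa = read_msa(config.msa)
        else:
            pool = refs.records + [
                r for r in candidates if r.id not in {x.id for x in refs.records}
            ]
            msa = align_msa(pool)
            write_msa(msa, outdir / "alignment.fasta")
        tree = bootstrap_supports(
            msa, n_replicates=config.bootstrap_replicates, seed=config.seed,
            model=config.distance_model,
        )
        with open(outdir / "tree.nwk", "w", newline="\n") as fh:
            fh.write(tree.newick() + "\n")
        calls = assign_subtypes(tree, refs, min_support=config.min_support)
        calls.sort(key=lambda a: a.candidate_id)
        _write_tsv(
            outdir / "assignments.tsv",
            ["candidate_id", "subtype", "support"],
            [
                [a.candidate_id, a.subtype,
                 f"{a.support:.1f}" if a.support is not None else "NA"]
                for a in calls
            ],
        )
        assignments_map = {
            a.candidate_id: a.subtype for a in calls if a.subtype != "unclassified"
        }
        n_classified = len(assignments_map)
        report["stages"]["classify"] = {
            "n_classified": n_classified,
            "n_unclassified": len(calls) - n_classified,
        }

    # --- stage 5: tandem arrays ------------------------------------------
    arrays = []
    if config.loci is not None and "tandem" not in config.skip_stages:
        loci = read_loci(config.loci, config.loci_format)
        locus_ids = {l.gene_id for l in loci}
        placed = [c for c in candidate_ids if c in locus_ids]
        arrays = detect_tandem_arrays(
            loci, placed, max_intervening=config.max_intervening,
            assignments=assignments_map,
        )
        _write_tsv(
            outdir / "arrays.tsv",
            ["scaffold_id", "n_members", "member_ids", "subtypes",
             "n_intervening", "orientation_consistent"],
            [
                [a.scaffold_id, a.size, ",".join(a.member_ids),
                 ",".join(f"{s}:{c}" for s, c in sorted(a.subtype_composition.items())),
                 a.n_intervening, a.orientation_consistent]
                for a in arrays
            ],
        )
        summary = tandem_summary(arrays, placed, assignments_map)
        with open(outdir / "tandem_summary.json", "w", newline="\n") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report["stages"]["tandem"] = {
            "n_arrays": len(arrays),
            "tandem_fraction": summary["tandem_fraction"],
        }

    # --- stage 6: expression clustering ----------------------------------
    if config.expression is not None and "cluster" not in config.skip_stages:
        matrix = read_expression(config.expression)
        params = config.cluster_params
        if params.seed != config.seed:
            params = ClusterParams(
                k=params.k, seed=config.seed, restarts=params.restarts,
                max_iter=params.max_iter, tol=params.tol,
            )
        result = kmeans_pearson(matrix, params)
        _write_tsv(
            outdir / "clusters.tsv",
            ["gene_id", "cluster"],
            [[g, c] for g, c in sorted(result.assignments.items())],
        )
        _write_tsv(
            outdir / "centroids.tsv",
            ["cluster"] + list(matrix.condition_ids),
            [
                [i + 1] + [f"{v:.6f}" for v in row]
                for i, row in enumerate(result.centroids)
            ],
        )
        report["stages"]["cluster"] = {
            "n_genes": len(result.assignments),
            "k": result.k,
            "inertia": round(result.inertia, 6),
        }
        if arrays:
            conc = cluster_array_concordance(result, arrays)
            conc.to_csv(outdir / "array_concordance.tsv", sep="\t", index=False,
                        lineterminator="\n")

    with open(outdir / "report.json", "w", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
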