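# serscan

A toolkit for motif-based, genome-wide prediction of cysteine-rich,
GPI-anchored surface-antigen gene families (ciliate *Ser*-type serotype
genes). Starting from a proteome FASTA, it chains six analysis stages:

1. **Motif scan** (`serscan.motif_scan`) — finds length-constrained
   cysteine blocks `C X≥6 C X≥1 C X≥1 C X≥1 C X≥1 C` within a 120-residue
   window (the 4-cysteine exploratory grammar with capped inner gaps is
   also supported).
2. **GPI signal gate** (`serscan.gpi_signal`) — a deterministic, rule-based
   classifier of the tripartite C-terminal anchor signal (small ω residue,
   polar spacer at ω+3..ω+8, hydrophobic Kyte–Doolittle tail from ω+9).
   Only "highly probable" signals pass. This is a documented checklist,
   not a reproduction of any trained HMM predictor, so candidate counts on
   real proteomes are not comparable with HMM-based tools.
3. **Repeat blocks** (`serscan.repeat_blocks`) — decomposes candidates into
   periodic repeat blocks and reports cysteines per block (the subtype
   signature: 6, 8 or 10) and block lengths.
4. **Phylogenetic classification** (`serscan.phylo_classify`) — bundled
   progressive aligner, p/Poisson distances, neighbor joining with
   deterministic tie-breaking, column-bootstrap supports, and clade-based
   subtype assignment against labelled references (plain `H/L/J` calls or
   starred `H*/L*/J*` sister-clade calls).
5. **Genome context** (`serscan.genome_context`) — tandem arrays of
   candidates on scaffolds (gene-rank adjacency, tolerated intervening
   genes) with purity/orientation summaries.
6. **Expression clustering** (`serscan.expression_cluster`) — k-means
   under Pearson-correlation distance over the 20 canonical growth /
   starvation / conjugation conditions, plus array–cluster concordance.

`serscan.synth_fixtures` generates synthetic proteomes, scaffold layouts
and expression matrices with machine-readable ground truth, so the whole
pipeline is testable offline.

## CLI

All stages are exposed as subcommands (`serscan --help`):

```
serscan scan     --fasta proteome.fasta --out scan.tsv
serscan gpi      --fasta proteome.fasta --out gpi.tsv
serscan blocks   --fasta candidates.fasta --out blocks.tsv
serscan classify --fasta candidates.fasta --ref-fasta refs.fasta \
                 --ref-labels refs.tsv --out assignments.tsv
serscan tandem   --loci genes.gff3 --candidates ids.txt --out arrays.tsv
serscan cluster  --expression expression.tsv --k 30 --out clusters.tsv
serscan simulate --seed 1 --outdir fixtures/
serscan pipeline --config pipeline.yaml
```

`serscan pipeline` runs every stage whose inputs are configured in the
YAML file and writes per-stage TSVs plus a JSON run report; reruns under a
fixed config and seed are byte-identical. Exit codes: 0 ok, 1 user error,
2 internal error.

## Notes

- Coordinates are 0-based half-open internally; GFF3 is converted on
  ingest.
- Published genome-scale counts (pattern hits, candidate totals) depend on
  a specific historical proteome release and an unavailable trained GPI
  predictor; the test suite therefore validates against planted synthetic
  truth and exhaustive oracles rather than those counts.
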