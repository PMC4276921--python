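# ngsdesk

A self-contained, desk-scale NGS analysis toolkit:

- **simulate** — diverged/mixed/recombinant genomes and error-bearing reads
  with recorded ground truth, so every downstream stage is testable with no
  external data.
- **map** — a minimal deterministic seed-and-extend read mapper (exact
  k-mer seeding, ungapped extension, best-identity placement); externally
  produced SAM is accepted everywhere as an alternative.
- **census** — taxonomic composition estimation by iterated random
  subsampling of reads, best-hit classification against a reference panel,
  and cross-iteration aggregation with percentile confidence intervals.
- **profile** — pileup-based SNV profiler: per-position A/C/G/T/del counts,
  thresholded SNV calls (each traceable to its supporting counts),
  consensus extraction, and sparse SNV-frequency profiles.
- **cluster** — SNV-profile comparison under pluggable distance metrics
  (euclidean, manhattan, canberra, pearson) and tree construction
  (single/complete/average linkage and neighbor joining), emitted as Newick.
- **phylosnp** — trees from binary sample-by-variant matrices, plus
  "shrunk genome" concatenation of merged flanking windows around SNVs with
  per-sample alleles substituted (a drop-in alignment for external tools).
- **clones** — quasispecies clone discovery by correlating co-occurring
  mutations within reads, with per-clone consensus sequences, frequency
  estimates, and a Sankey-ready link table.
- **recomb** — recombination detection from per-reference coverage
  dominance along mutually aligned (equal-length) references, reporting
  segments and candidate breakpoints.

All file formats are plain text: FASTA, FASTQ, a minimal SAM dialect
(mandatory columns; CIGAR ops M/=/X/I/D/S), Newick, and `#`-headed TSV
tables. Internal coordinates are 0-based half-open; SAM POS and all
`*_1based` TSV columns are converted at the I/O boundary only.

## CLI

One entry point with one subcommand per stage; every run writes a
`config.txt` echo of its effective parameters next to its outputs, logs to
stderr, and is byte-deterministic under a fixed `--seed`.

```sh
# simulate a 3-genome mixture and reads
ngsdesk simulate --seed 1 --n-genomes 3 --genome-length 10000 \
    --snv-rate 0.05 --weights 0.6,0.3,0.1 --n-reads 30000 --out-dir sim/

# subsampled census against the simulated panel
ngsdesk census --reads sim/reads.fastq --refs sim/genomes.fasta \
    --taxa sim/taxa.tsv --n 250 --iterations 20 --seed 1 --out-dir census/

# map, profile, call SNVs
ngsdesk map --refs ref.fasta --reads sample.fastq --out-dir mapped/
ngsdesk profile --sam mapped/alignments.sam --ref ref.fasta \
    --min-depth 10 --min-freq 0.05 --out-dir prof/

# cluster SNV-frequency profiles from several samples
ngsdesk cluster --profiles a/profile.tsv --profiles b/profile.tsv \
    --metric euclidean --linkage average --out-dir clust/

# SNV trees and shrunk genomes
ngsdesk phylosnp --ref ref.fasta --snvs a/snvs.tsv --snvs b/snvs.tsv \
    --flank 10 --out-dir phylo/

# clone discovery and recombination detection
ngsdesk clones --sam mapped/alignments.sam --ref ref.fasta \
    --snvs prof/snvs.tsv --out-dir clones/
ngsdesk recomb --refs parents.fasta --reads sample.fastq --out-dir rec/
```

A key-value config file (`key = value` per line) can supply defaults:
`ngsdesk --config run.cfg simulate --out-dir sim/`.

Exit codes: 0 success, 2 usage error, 1 runtime failure (single-line
`ErrorClass: message` on stderr).

## Design notes

- The mapper is intentionally minimal (ungapped, forward-strand,
  substitution-only, deterministic tie-breaking); it exists so the toolkit
  runs self-contained. Real gapped alignments enter through SAM import.
- The census samples without replacement within an iteration; iterations
  are mutually independent (iteration *i* uses `seed + i`); the CI is the
  2.5/97.5 percentile interval across iterations.
- SNV-profile distances are computed over the union of variant positions,
  with implicit frequency 0 at covered-but-reference positions; positions
  uncovered in either sample are dropped from that pair's comparison.
- Variant keys are allele-aware `(position, alt_base)` pairs: two samples
  with different alternate bases at one site differ in two matrix columns.
- Clone linkage uses support = n11/(n11+n10+n01) (Jaccard on alt-carrying
  reads) and transitive closure via connected components.
- Recombination attribution counts a read toward every reference achieving
  its best identity, so zero-divergence references can never show
  confident dominance (no hallucinated breakpoints).
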