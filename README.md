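# plasmidqc

Validation of assembled, cloned or edited plasmids against their designed
reference sequences, from nanopore long-read sequencing data.

## Who this is for

Biofoundries and cloning labs routinely need to answer one question per
construct: *is the plasmid I built the plasmid I designed?* After a
multiplexed nanopore run (e.g. a rapid-barcoding library on a Flongle
flow cell), each barcode holds the reads of one sample. `plasmidqc`
takes the demultiplexed FASTQ files, the designed references
(GenBank/FASTA) and a sample sheet, and assigns every sample one of four
verdicts — **pass**, **warning**, **fail**, or **low coverage** — with
machine-readable reasons, a simplified VCF of small variants, a
variant-call consensus FASTA, and coverage tracks.

A second workflow maps the constituent DNA **parts** of a construct
(e.g. Golden Gate fragments) onto any assembled or consensus sequence,
reporting their order, orientation and identity — useful for diagnosing
part mix-ups, recombination and overhang misannealing.

A built-in read **simulator** with truth SAM output makes the entire
pipeline testable end to end without external data or an external
aligner.

## The method

For a (usually circular) reference of length *L* and per-position read
depth *d(p)* computed from the alignments (deleted bases in a read count
as covered; all positions taken mod *L* on circles):

- **Coverage gate.** Samples with mean depth
  $\bar d = \tfrac1L\sum_p d(p) < 30\times$ are *low coverage* —
  too few reads to judge.
- **Structural evidence.** Maximal runs with *d(p)* = 0 are
  zero-coverage sections (the alignment signature of a construct
  deletion). Per read, the *longest unaligned interval* is the largest
  run of read bases not aligned in any of its records (insertions +
  clips, primary and supplementary merged); a construct insertion makes
  a majority of reads (> 0.5) carry an interval ≥ 50 nt.
- **Small variants.** A pileup majority caller: at each column with
  depth ≥ 10, the most frequent non-reference symbol is called iff its
  fraction of the column depth is ≥ 0.5. Adjacent substitutions merge
  into MNVs, deletion runs into one deletion; indels are VCF
  left-anchored. Variants overlapping a homopolymer run of ≥ 4 identical
  bases (or indels of base X adjacent to a run of X of length ≥ 3) are
  flagged as the known systematic nanopore error mode.
- **Consensus.** Called variants applied to the reference; the length
  must stay within max(10 nt, 1% of *L*).
- **Verdict**, in strict precedence: low coverage → fail (any
  zero-coverage section, insert-read majority, consensus length out of
  tolerance, or any confident non-homopolymer variant) → warning
  (variants exist but all are homopolymer-flagged) → pass.

Part mapping finds candidate loci by exact *k*-mer seeding (*k* = 15) on
both strands (circular targets are searched on the doubled sequence) and
scores them by unit-cost edit alignment; hits need identity ≥ 0.8 over
≥ 50% of the part.

## Worked example

Simulate a complete 8-barcode validation run (one scenario per defect
class) and analyze it:

```
$ plasmidqc simulate --out sim --seed 7 --n-reads 80
simulated 8 barcode(s) into sim

$ plasmidqc analyze --fastq-dir sim --sam-dir sim \
    --references sim/reference.fasta \
    --sample-sheet sim/sample_sheet.csv --circular --out qc
barcode01  ok                 pass
barcode02  point_mutation     fail
barcode03  deletion_500       fail
barcode04  insertion_500      fail
barcode05  part_replacement   fail
barcode06  low_reads          low_coverage
barcode07  homopolymer_indel  warning
barcode08  mixed_5050         fail

$ cat qc/summary.csv
barcode,sample_name,outcome,mean_depth,n_variants,n_flagged,insert_fraction,length_difference
barcode01,ok,pass,53.465,0,0,0.0,0
barcode02,point_mutation,fail,53.183,1,0,0.0,0
barcode03,deletion_500,fail,51.342,0,0,0.0,0
barcode04,insertion_500,fail,51.255,0,0,0.7875,0
barcode05,part_replacement,fail,46.384,0,0,0.8625,0
barcode06,low_reads,low_coverage,6.943,0,0,0.0,0
barcode07,homopolymer_indel,warning,55.553,1,1,0.0,-1
barcode08,mixed_5050,fail,51.087,0,0,0.725,0
```

Reading the table: the correct construct passes; the clean point
mutation is a confident non-homopolymer variant, hence fail; the 500 nt
deletion produces a zero-coverage section; the 500 nt insertion and the
polyclonal 50:50 mixture leave a majority of reads (79% / 73%) with a
large unaligned segment; ten reads give only ~7× mean depth (below the
30× gate); the single-base deletion inside a homopolymer is called but
flagged as the typical systematic sequencing error, hence only a
warning (consensus 1 nt shorter, within tolerance).

Each barcode also gets `*.report.json` (full metrics + effective
config), `*.vcf`, `*.consensus.fasta` and `*.coverage.bedgraph`. The
`preview` subcommand computes read statistics and length histograms
without alignments; `assembly` maps part FASTA files onto an assembled
target. Exit code is 0 whatever the verdicts are (a failed sample is a
result, not an error); usage and input errors exit 2.

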