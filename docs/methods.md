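# Methods

## Problem and model

A sequenced plasmid sample is compared against its designed reference
sequence. Differences fall into two regimes with different observables:

- **Small variants** (SNVs, MNVs, short indels) appear *inside* read
  alignments, as mismatching pileup columns or short I/D CIGAR
  operations, and are called from the pileup.
- **Structural variants** (large deletions, insertions, replacements)
  do not appear in the pileup at all: long-read aligners split a read at
  a structural breakpoint into a primary plus supplementary alignment
  with the intervening bases soft-clipped. Their observables are
  therefore *coverage topology* (a deleted region has no spanning reads
  → a zero-coverage section) and *read geometry* (an inserted region
  leaves a long unaligned interval in most reads that cross it). The
  variant table deliberately excludes structural variants; structural
  evidence feeds the verdict directly.

All internal coordinates are 0-based half-open; 1-based coordinates
exist only at the GenBank and VCF boundaries. Circular topology is
handled by modulo arithmetic on reference positions: alignment spans may
run past the sequence end and wrap, zero-coverage runs touching both
ends merge into one origin-wrapping section, and homopolymer runs may
cross the origin. The package does not rotate or double references for
alignment — that is the upstream aligner's concern.

## Per-sample pipeline

1. **Filter** reads by length ≥ 500 nt and mean quality ≥ Q8. Mean read
   quality is the probability-space mean (convert each Phred score to an
   error probability, average, convert back), which penalizes a read's
   worst bases more than an arithmetic Phred mean — the convention of
   the common long-read filtering tools. The cutoffs discard adapter
   fragments while keeping short plasmid fragments.
2. **Coverage** counts, per reference position, the alignment records
   whose reference-consuming span (M/=/X/D) covers it. A deleted base
   (D) counts as covered: a read spanning a small deletion still attests
   the region exists once; only true absence of spanning reads should
   create zero-coverage sections.
3. **Unaligned intervals** are computed per read after merging primary
   and supplementary records onto original read coordinates (reverse
   alignments are mapped back through the read length). Without the
   merge, a read split across one breakpoint would be double-counted as
   two half-unaligned reads.
4. **Variant calling** is a per-column majority vote: at depth ≥ 10 the
   single most frequent non-reference symbol (base or deletion mark) is
   called iff its fraction of the column depth is ≥ 0.5. Ties at exactly
   0.5 are called — this is the operative rule at the boundary.
   Insertion alleles obey the same rule against the anchoring column's
   depth. Adjacent substitution calls merge into one MNV; adjacent
   deletion calls merge into one deletion, left-anchored on the
   preceding reference base (VCF convention; a deletion starting at
   position 0 of a linear reference is anchored on the following base).
   Only the top alt per column is considered: multi-allelic columns
   (mixed samples) are out of scope and surface as sub-threshold noise.
5. **Homopolymer flagging** marks variants whose affected reference
   interval overlaps a run of ≥ 4 identical bases, and indels of base X
   immediately adjacent to a run of X of length ≥ 3. Flagged variants
   are treated as probable systematic sequencing errors, not assembly
   errors.
6. **Consensus** applies the called variants left to right; regions
   with zero coverage keep reference bases (their detection is the
   verdict's job, so the consensus never silently hides missing
   sequence). Length tolerance: |Δ| ≤ max(10 nt, 1% of reference).
7. **Verdict**, strict precedence:
   1. mean depth < 30× → `low_coverage`;
   2. any zero-coverage section, insert-read fraction > 0.5, consensus
      length out of tolerance, or more than 0 non-flagged variants →
      `fail` (one reason per triggered condition);
   3. any variants at all (necessarily all flagged) → `warning`;
   4. otherwise `pass`.

   The 30× gate uses mean depth over the whole reference, not minimum
   depth — locally missing sequence is already policed by the
   zero-coverage rule. "Majority" is strict (> 0.5). The non-flagged
   variant limit defaults to 0 — a confident clonal non-homopolymer
   variant is a real construct error — and is configurable for laxer
   regimes.

## Defaults

| parameter | default | unit | why |
|---|---|---|---|
| min_read_length | 500 | nt | drop adapter/fragment debris |
| min_mean_quality | 8 | Phred | typical long-read pass threshold |
| histogram_bin_width | 250 | nt | resolves kb-scale length shifts |
| min_mean_depth | 30 | × | the coverage gate |
| min_insert_length | 50 | nt | separates real inserts from terminal alignment fuzz |
| insert_majority_fraction | 0.5 | — | "majority" = strictly more than half |
| min_depth | 10 | × | below this a column is uninformative |
| min_fraction | 0.5 | — | clonal variants sit near 1.0; random error cannot reach 0.5 |
| min_run | 4 | nt | homopolymer length with elevated indel error |
| tolerance_abs / tolerance_rel | 10 nt / 1% | — | consensus length envelope |
| seed_k / min_identity / part_coverage | 15 / 0.8 / 0.5 | — | 15-mers are near-unique in 10 kb plasmids; 0.8 tolerates consensus indel noise |

All are overridable through one flat TOML config; every report JSON
embeds the effective configuration.

## Part mapping

Candidate loci come from exact k-mer seed matches clustered by
diagonal; each candidate window is scored by unit-cost edit alignment
(edlib), with identity = matches / aligned columns after trimming
unaligned alignment ends, and part coverage = aligned part fraction.
Circular targets are searched on the doubled sequence; hits longer than
the target are rejected and coordinates are reported modulo the target
length. Non-overlapping hits (identity ≥ 0.8, coverage ≥ 0.5) are kept
best-first, so duplicated parts yield multiple hits. De novo assembly
is out of scope: the target may be the variant-call consensus or any
externally assembled FASTA.

## Simulator

The generator emulates a rapid-barcoding nanopore run on a circular
plasmid: uniform fragmentation start positions on the circle, lognormal
read lengths (median ≈ 2 kb, log-sd 0.35, clipped to [200 nt, template
length]), and per-base errors — substitution 3%, insertion 1%, deletion
2%, with the deletion probability multiplied by 1.5^(run−1) inside a
homopolymer run of length *run* (capped below 0.5), reproducing the
dominant systematic nanopore error mode. Qualities are drawn around
Q12. These rates describe a mid-quality R9-class run; they are
deliberately pessimistic enough that random error stays far below the
0.5 calling fraction at validated coverage.

Scripted defects edit the reference into a template (SNV, interval
deletion, insertion, replacement, or a weighted mixture of sub-edits
for polyclonal samples). Reads are simulated in template space; truth
alignments are lifted into reference space through the edit's
coordinate map. Edits shorter than 50 nt are lifted *into* the CIGAR
(D/I ops, or mismatching M columns for same-length replacements), the
way aligners report small indels; edits of ≥ 50 nt split reads into
soft-clipped primary + supplementary records at the breakpoints, the
way long-read aligners report structural variants. Aligned blocks
shorter than 30 nt are folded into clips (a real aligner would not
anchor them). This lift-over is what makes zero-coverage sections the
observable signature of deletions and long unaligned intervals the
signature of insertions, rather than artifacts of the generator.

The canonical validation run covers eight scenarios on a 3 kb circular
reference at 80 reads (≈ 50× mean depth): correct construct, point
mutation, 500 nt deletion, 500 nt insertion, 500 nt replacement, 10
reads only, a single-base homopolymer deletion, and a 50:50 mixture.
The mixture pools two clones carrying distinct 500 nt insertions: with
realistic noise, a 50:50 correct/point-variant mixture sits
systematically just *below* the 0.5 calling fraction (noise inflates
the depth denominator), so it surfaces as sub-threshold noise — the
documented behaviour for mixtures — whereas a pool of two structurally
defective clones fails deterministically via the insert-majority rule.

### What the simulator does not emulate

Signal-level artifacts, basecaller-realistic quality strings, chimeric
and adapter reads, barcode cross-talk, strand bias, and
coverage non-uniformity from fragmentation chemistry. Passing tests
therefore demonstrate the *analysis logic* — coverage topology, read
geometry, majority calling, verdict precedence — under a clean
generative model, not robustness to every real-world artifact. The
truth SAM stands in for an external aligner; an adapter can align the
emitted FASTQ with a real aligner, whose output the same analysis
consumes unchanged.

## Numerical and degenerate-input choices

- Column tie between two alt symbols: the lexicographically larger
  symbol wins (deterministic).
- A variant whose reference interval overlaps a previously applied one
  (possible when a deletion's anchor base also carries a substitution
  call) is dropped with a logged warning before consensus building.
- Empty read sets and barcodes with no FASTQ yield a `low_coverage`
  verdict with reason `no_reads` ("no data" in the report), never an
  exception; an empty read set is also a legal filter output.
- Whole-reference deletions have no anchor base and are not emitted as
  VCF records (they are structural by definition).
- N50 is the smallest length present in the set such that reads at
  least that long hold ≥ half the bases.
- Simulated runs are byte-reproducible from (global seed, scenario
  seed, barcode index) via numpy's seed-sequence spawning.

## Test problem sizes

The suite runs everything at desk scale: 3 kb references, 80-read
barcodes (≈ 50×), 200–500-read simulations for rate measurements,
1000-CIGAR and 200-pileup oracle sweeps. These sizes give the majority
statistics comfortable margins (e.g. the insertion scenario's insert
fraction concentrates near 0.69, >3σ above the 0.5 majority threshold)
while keeping the full suite in the tens of seconds.

## Known limitations

- Mixed samples are detected only when their defects are structural;
  balanced point-variant mixtures are below the calling threshold by
  design (deconvolution is out of scope).
- The caller is haploid and quality-unaware: no genotype likelihoods,
  no multi-allelic records, no phasing.
- Coverage is not mapping-quality-weighted; repeats within a plasmid
  can inflate apparent depth.
- Part mapping reports placements, not overhang/fusion-site inference.
- BAM/CRAM input is not parsed; convert to SAM upstream.
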