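"""Pileup-based small-variant calling, homopolymer flagging, consensus
building and the simplified VCF dialect.

The caller is a per-column majority voter: at every reference column
with sufficient depth, the single most frequent non-reference symbol
(a base or the deletion mark) is called iff its fraction of the column
depth reaches ``min_fraction``; the tie rule is ≥, so an exactly 50:50
mixed column is called. Adjacent substitution calls merge into one MNV,
runs of deletion calls merge into one deletion, and indels are reported
left-anchored on the preceding reference base, VCF-style. Structural
variants never reach the pileup (large events surface as clipped or
split alignments) and are therefore absent from the VCF by
construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io import ReadAlignment, ReferenceRecord, InputError, ValidationError

DELETION_MARK = "*"

DEFAULT_MIN_FRACTION = 0.5
DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_RUN = 4
DEFAULT_TOLERANCE_ABS = 10
DEFAULT_TOLERANCE_REL = 0.01


@dataclass
class PileupColumn:
    """Per-reference-position tally of observed symbols.

    ``insertion_counts`` holds sequences inserted immediately after this
    position (the VCF anchoring convention).
    """

    position: int
    ref_base: str
    base_counts: Counter = field(default_factory=Counter)
    insertion_counts: Counter = field(default_factory=Counter)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class Variant:
    """A called difference between sample and design, VCF-normalized."""

    position: int  # 0-based offset of the first REF base
    ref_allele: str
    alt_allele: str
    depth: int
    alt_fraction: float
    kind: str  # SNV | MNV | insertion | deletion
    homopolymer_flag: bool = False

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValidationError("variant alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValidationError("ref and alt alleles are identical")


@dataclass(frozen=True)
class ConsensusResult:
    """The variant-call consensus sequence and its length check."""

    sequence: str
    length: int
    length_difference: int
    within_tolerance: bool


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

def build_pileup(
    alignments: Iterable[ReadAlignment], reference: ReferenceRecord
) -> list[PileupColumn]:
    """Build pileup columns from mapped alignments carrying read sequences.

    Only reference positions with nonzero spanning depth get a column.
    Insertions are anchored to the preceding reference position; on
    circular references positions wrap modulo the length.
    """
    n = reference.length
    columns: dict[int, PileupColumn] = {}

    def col(pos: int) -> PileupColumn:
        pos %= n
        if pos not in columns:
            columns[pos] = PileupColumn(position=pos, ref_base=reference.sequence[pos])
        return columns[pos]

    for aln in alignments:
        if not aln.mapped:
            continue
        seq = aln.read_sequence
        if seq is None:
            raise InputError(
                f"alignment of {aln.read_id!r} carries no read sequence; "
                "pileup requires SEQ"
            )
        rpos, qpos = aln.start, 0
        for op, length in aln.cigar:
            if op in ("M", "=", "X"):
                for i in range(length):
                    col(rpos + i).base_counts[seq[qpos + i]] += 1
                rpos += length
                qpos += length
            elif op == "D":
                for i in range(length):
                    col(rpos + i).base_counts[DELETION_MARK] += 1
                rpos += length
            elif op == "I":
                anchor = (rpos - 1) % n
                if rpos > aln.start:  # insertions before any aligned base are clips in disguise
                    col(anchor).insertion_counts[seq[qpos : qpos + length]] += 1
                qpos += length
            elif op in ("S", "H"):
                if op == "S":
                    qpos += length
            elif op == "N":
                rpos += length
        if qpos != len(seq):
            raise InputError(
                f"alignment of {aln.read_id!r}: CIGAR walks {qpos} bases of a "
                f"{len(seq)} nt sequence"
            )
    return [columns[p] for p in sorted(columns)]


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def _column_call(column: PileupColumn, min_fraction: float) -> str | None:
    """The winning non-reference symbol of one column, or None."""
    candidates = [
        (count, sym)
        for sym, count in column.base_counts.items()
        if sym != column.ref_base
    ]
    if not candidates:
        return None
    count, sym = max(candidates, key=lambda t: (t[0], t[1]))
    if count / column.depth >= min_fraction:
        return sym
    return None


def call_variants(
    pileup: Sequence[PileupColumn],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
    reference: ReferenceRecord | None = None,
) -> list[Variant]:
    """Call small variants from a pileup by per-column majority vote.

    Adjacent substitution calls merge into an MNV; adjacent deletion
    calls merge into one deletion; insertion alleles obey the same
    fraction rule against insertion_counts. ``reference`` supplies the
    anchor base for indels at column gaps (optional; the preceding
    pileup column is used when available).
    """
    if not (0 < min_fraction <= 1):
        raise ValidationError("min_fraction must be in (0, 1]")
    if min_depth < 1:
        raise ValidationError("min_depth must be ≥ 1")

    by_pos = {c.position: c for c in pileup}

    def anchor_base(pos: int) -> str | None:
        if pos in by_pos:
            return by_pos[pos].ref_base
        if reference is not None:
            if reference.circular:
                return reference.sequence[pos % reference.length]
            if 0 <= pos < reference.length:
                return reference.sequence[pos]
        return None

    # pass 1: per-column substitution / deletion calls
    sub_calls: list[tuple[int, str, str, int, float]] = []  # pos, ref, alt, depth, frac
    del_calls: list[tuple[int, str, int, float]] = []  # pos, ref, depth, frac
    ins_variants: list[Variant] = []
    for column in sorted(pileup, key=lambda c: c.position):
        if column.depth >= min_depth:
            sym = _column_call(column, min_fraction)
            if sym is not None:
                frac = column.base_counts[sym] / column.depth
                if sym == DELETION_MARK:
                    del_calls.append((column.position, column.ref_base, column.depth, frac))
                else:
                    sub_calls.append(
                        (column.position, column.ref_base, sym, column.depth, frac)
                    )
            # insertion alleles, by the same rule on the same column depth
            if column.insertion_counts:
                count, seq = max(
                    ((c, s) for s, c in column.insertion_counts.items()),
                    key=lambda t: (t[0], t[1]),
                )
                if count / column.depth >= min_fraction:
                    ins_variants.append(
                        Variant(
                            position=column.position,
                            ref_allele=column.ref_base,
                            alt_allele=column.ref_base + seq,
                            depth=column.depth,
                            alt_fraction=count / column.depth,
                            kind="insertion",
                        )
                    )

    variants: list[Variant] = list(ins_variants)

    # pass 2: merge adjacent substitutions into MNVs
    i = 0
    while i < len(sub_calls):
        j = i
        while j + 1 < len(sub_calls) and sub_calls[j + 1][0] == sub_calls[j][0] + 1:
            j += 1
        run = sub_calls[i : j + 1]
        ref = "".join(r[1] for r in run)
        alt = "".join(r[2] for r in run)
        variants.append(
            Variant(
                position=run[0][0],
                ref_allele=ref,
                alt_allele=alt,
                depth=min(r[3] for r in run),
                alt_fraction=min(r[4] for r in run),
                kind="SNV" if len(run) == 1 else "MNV",
            )
        )
        i = j + 1

    # pass 3: merge adjacent deletion calls, left-anchor on preceding base
    i = 0
    while i < len(del_calls):
        j = i
        while j + 1 < len(del_calls) and del_calls[j + 1][0] == del_calls[j][0] + 1:
            j += 1
        run = del_calls[i : j + 1]
        first = run[0][0]
        deleted = "".join(r[1] for r in run)
        prev = anchor_base(first - 1) if first > 0 else None
        if prev is not None:
            variants.append(
                Variant(
                    position=first - 1,
                    ref_allele=prev + deleted,
                    alt_allele=prev,
                    depth=min(r[2] for r in run),
                    alt_fraction=min(r[3] for r in run),
                    kind="deletion",
                )
            )
        else:
            # deletion at reference start on a linear record: anchor on the
            # following base (VCF permits either for edge deletions)
            nxt = anchor_base(run[-1][0] + 1)
            if nxt is None:
                i = j + 1
                continue
            variants.append(
                Variant(
                    position=first,
                    ref_allele=deleted + nxt,
                    alt_allele=nxt,
                    depth=min(r[2] for r in run),
                    alt_fraction=min(r[3] for r in run),
                    kind="deletion",
                )
            )
        i = j + 1

    variants.sort(key=lambda v: (v.position, v.kind))
    return variants


# ---------------------------------------------------------------------------
# Homopolymer flagging
# ---------------------------------------------------------------------------

def homopolymer_runs(reference: ReferenceRecord, min_len: int = 2) -> list[tuple[int, int, str]]:
    """Maximal runs (start, end, base) of identical bases of length ≥ min_len;
    a run crossing the origin of a circular reference is reported with
    end > length."""
    seq = reference.sequence
    n = len(seq)
    scan = seq + seq if reference.circular else seq
    runs: list[tuple[int, int, str]] = []
    i = 0
    limit = len(scan)
    while i < limit:
        j = i
        while j < limit and scan[j] == scan[i]:
            j += 1
        if j - i >= min_len and i < n:
            runs.append((i, min(j, i + n), scan[i]))
        i = j
    if reference.circular:
        # drop duplicates fully contained in the second copy's view
        runs = [r for r in runs if r[0] < n]
        # a run starting at 0 that is the tail of a wrapping run is covered
        # by the wrapping entry; remove it
        wrapping = [r for r in runs if r[1] > n]
        if wrapping:
            tail_end = wrapping[0][1] - n
            runs = [r for r in runs if not (r[0] == 0 and r[1] <= tail_end)]
    return runs


def _affected_interval(variant: Variant) -> tuple[int, int]:
    """Reference interval a variant touches (0-based half-open)."""
    if variant.kind == "deletion":
        if len(variant.ref_allele) > len(variant.alt_allele) and variant.ref_allele.startswith(
            variant.alt_allele
        ):
            return (variant.position + 1, variant.position + len(variant.ref_allele))
        return (variant.position, variant.position + len(variant.ref_allele) - 1)
    if variant.kind == "insertion":
        return (variant.position, variant.position + 1)
    return (variant.position, variant.position + len(variant.ref_allele))


def _indel_bases(variant: Variant) -> str:
    """The inserted or deleted sequence of an indel, empty for substitutions."""
    ref, alt = variant.ref_allele, variant.alt_allele
    if variant.kind == "insertion" and alt.startswith(ref):
        return alt[len(ref) :]
    if variant.kind == "deletion":
        if ref.startswith(alt):
            return ref[len(alt) :]
        if ref.endswith(alt):
            return ref[: len(ref) - len(alt)]
    return ""


def flag_homopolymers(
    variants: Sequence[Variant],
    reference: ReferenceRecord,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[Variant]:
    """Mark variants in homopolymer context — the dominant systematic
    nanopore indel error.

    A variant is flagged iff its affected reference interval overlaps a
    run of ≥ ``min_run`` identical bases, or it inserts/deletes base X
    immediately adjacent to a run of X of length ≥ ``min_run`` − 1.
    """
    if min_run < 2:
        raise ValidationError("min_run must be ≥ 2")
    n = reference.length
    runs = homopolymer_runs(reference, min_len=min_run - 1)

    def overlaps(lo: int, hi: int, rlo: int, rhi: int) -> bool:
        if reference.circular:
            # compare on the doubled circle
            for shift in (0, n):
                if max(lo + shift, rlo) < min(hi + shift, rhi):
                    return True
                if max(lo, rlo + shift) < min(hi, rhi + shift):
                    return True
            return False
        return max(lo, rlo) < min(hi, rhi)

    out: list[Variant] = []
    for v in variants:
        lo, hi = _affected_interval(v)
        flagged = any(
            rhi - rlo >= min_run and overlaps(lo, hi, rlo, rhi) for rlo, rhi, _ in runs
        )
        if not flagged and v.kind in ("insertion", "deletion"):
            bases = _indel_bases(v)
            if bases and len(set(bases)) == 1:
                x = bases[0]
                # adjacency: expand the indel locus by one base on each side
                elo, ehi = lo - 1, hi + 1
                if elo < 0:
                    if reference.circular:
                        elo, ehi = elo + n, ehi + n
                    else:
                        elo = 0
                flagged = any(
                    base == x and rhi - rlo >= min_run - 1 and overlaps(elo, ehi, rlo, rhi)
                    for rlo, rhi, base in runs
                )
        out.append(replace(v, homopolymer_flag=flagged))
    return out


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def build_consensus(
    reference: ReferenceRecord,
    variants: Sequence[Variant],
    tolerance_abs: int = DEFAULT_TOLERANCE_ABS,
    tolerance_rel: float = DEFAULT_TOLERANCE_REL,
) -> ConsensusResult:
    """Apply non-overlapping variants to the reference, left to right.

    Zero-coverage regions keep reference bases — their detection is the
    verdict's job, not the consensus builder's.
    """
    ordered = sorted(variants, key=lambda v: v.position)
    for a, b in zip(ordered, ordered[1:]):
        a_lo, a_hi = a.position, a.position + len(a.ref_allele)
        b_lo = b.position
        if b_lo < a_hi:
            raise ValidationError(
                f"overlapping variants at positions {a.position} and {b.position}"
            )
    pieces: list[str] = []
    cursor = 0
    for v in ordered:
        pieces.append(reference.sequence[cursor : v.position])
        pieces.append(v.alt_allele)
        cursor = v.position + len(v.ref_allele)
    pieces.append(reference.sequence[cursor:])
    seq = "".join(pieces)
    diff = len(seq) - reference.length
    return ConsensusResult(
        sequence=seq,
        length=len(seq),
        length_difference=diff,
        within_tolerance=consensus_length_ok(
            diff, reference.length, tolerance_abs, tolerance_rel
        ),
    )


def consensus_length_ok(
    length_difference: int,
    reference_length: int,
    tolerance_abs: int = DEFAULT_TOLERANCE_ABS,
    tolerance_rel: float = DEFAULT_TOLERANCE_REL,
) -> bool:
    """True iff |Δlength| ≤ max(tolerance_abs, tolerance_rel × reference length)."""
    if tolerance_abs < 0 or tolerance_rel < 0:
        raise ValidationError("tolerances must be non-negative")
    allowed = max(tolerance_abs, tolerance_rel * reference_length)
    return abs(length_difference) <= allowed


def consensus_length_check(
    consensus: ConsensusResult,
    reference: ReferenceRecord,
    tolerance_abs: int = DEFAULT_TOLERANCE_ABS,
    tolerance_rel: float = DEFAULT_TOLERANCE_REL,
) -> bool:
    return consensus_length_ok(
        consensus.length_difference, reference.length, tolerance_abs, tolerance_rel
    )


def write_consensus_fasta(consensus: ConsensusResult, name: str, path) -> None:
    with open(path, "w", encoding="ascii") as handle:
        handle.write(f">{name}\n")
        seq = consensus.sequence
        for i in range(0, len(seq), 70):
            handle.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Simplified VCF
# ---------------------------------------------------------------------------

def write_simplified_vcf(
    variants: Sequence[Variant], reference: ReferenceRecord, path
) -> None:
    """Write a minimal VCF 4.2: DP and AF in INFO, FILTER ``homopolymer``
    for flagged variants, records sorted by POS."""
    with open(path, "w", encoding="ascii") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write(f"##contig=<ID={reference.id},length={reference.length}>\n")
        handle.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        handle.write(
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">\n'
        )
        handle.write(
            '##FILTER=<ID=homopolymer,Description="Variant in homopolymer context">\n'
        )
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.position):
            filt = "homopolymer" if v.homopolymer_flag else "PASS"
            handle.write(
                f"{reference.id}\t{v.position + 1}\t.\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\t{filt}\tDP={v.depth};AF={v.alt_fraction:.6g}\n"
            )


def _variant_kind(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


def read_simplified_vcf(path) -> list[Variant]:
    """Re-parse a simplified VCF written by :func:`write_simplified_vcf`."""
    variants: list[Variant] = []
    with open(path, encoding="ascii") as handle:
        for line in handle:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise InputError(f"short VCF record in {path}: {line!r}")
            _, pos, _, ref, alt, _, filt, info = fields[:8]
            kv = dict(item.split("=", 1) for item in info.split(";") if "=" in item)
            variants.append(
                Variant(
                    position=int(pos) - 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    depth=int(kv.get("DP", 0)),
                    alt_fraction=float(kv.get("AF", 0.0)),
                    kind=_variant_kind(ref, alt),
                    homopolymer_flag=filt == "homopolymer",
                )
            )
    return variants
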