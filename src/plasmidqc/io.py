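"""Input parsing and validation for references, reads, alignments and sample sheets.

All internal coordinates are 0-based half-open; 1-based coordinates appear
only at the GenBank/VCF boundary. Sequences are normalized to uppercase
A/C/G/T/N on input.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

logger = logging.getLogger("plasmidqc")

_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

#: CIGAR operation characters in pysam integer-code order.
CIGAR_OPS = "MIDNSHP=X"
#: Operations that consume the read (query) sequence.
QUERY_OPS = frozenset("MIS=X")
#: Operations that consume reference positions.
REF_OPS = frozenset("MDN=X")
#: Operations aligning read bases to reference bases.
ALIGNED_OPS = frozenset("M=X")


class InputError(Exception):
    """An input file is missing, unreadable, or malformed."""


class ValidationError(Exception):
    """Parsed input violates a domain invariant."""


def _normalize_sequence(seq: str, context: str) -> str:
    seq = seq.upper()
    if _NON_ACGTN.search(seq):
        n_bad = len(_NON_ACGTN.findall(seq))
        logger.warning(
            "%s: %d non-ACGTN character(s) replaced by N", context, n_bad
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


@dataclass(frozen=True)
class ReferenceRecord:
    """A designed plasmid sequence: the target of all comparisons.

    Features use 0-based half-open coordinates; a feature crossing the
    origin of a circular record is stored as two sub-intervals sharing
    one label.
    """

    id: str
    sequence: str
    circular: bool = False
    features: tuple[tuple[str, int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"reference {self.id!r} has an empty sequence")
        if not set(self.sequence) <= _VALID_BASES:
            raise ValidationError(
                f"reference {self.id!r} contains non-ACGTN characters"
            )
        for label, start, end, _strand in self.features:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValidationError(
                    f"feature {label!r} interval ({start}, {end}) outside "
                    f"reference {self.id!r} of length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SampleSheetEntry:
    """One demultiplexed sample: a barcode, its name, and its designed reference."""

    barcode: str
    sample_name: str
    reference_id: str


@dataclass(frozen=True)
class Read:
    """A basecalled read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValidationError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAlignment:
    """One read's placement on a reference with its edit structure.

    ``cigar`` is a tuple of ``(op, length)`` with op in ``MIDNSHP=X``.
    Unmapped placeholders keep the read length but carry no cigar and an
    undefined (-1) start.
    """

    read_id: str
    reference_id: str
    start: int
    cigar: tuple[tuple[str, int], ...]
    strand: str  # "forward" | "reverse"
    mapped: bool
    read_length: int
    is_supplementary: bool = False
    read_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.mapped:
            consumed = sum(
                n for op, n in self.cigar if op in QUERY_OPS or op == "H"
            )
            if consumed != self.read_length:
                raise ValidationError(
                    f"alignment of {self.read_id!r}: CIGAR consumes {consumed} "
                    f"read bases but read_length={self.read_length}"
                )
        elif self.cigar:
            raise ValidationError(
                f"unmapped placeholder {self.read_id!r} carries a CIGAR"
            )

    @property
    def reference_span(self) -> int:
        """Number of reference positions consumed (M/=/X/D/N)."""
        return sum(n for op, n in self.cigar if op in REF_OPS)

    @property
    def end(self) -> int:
        """Exclusive reference end; may exceed the reference length on circles."""
        return self.start + self.reference_span


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

def _features_from_seqrecord(record, length: int):
    feats = []
    for f in record.features:
        label = (
            f.qualifiers.get("label", [None])[0]
            or f.qualifiers.get("gene", [None])[0]
            or f.type
        )
        strand = f.location.strand or 0
        if isinstance(f.location, CompoundLocation):
            parts = f.location.parts
        else:
            parts = [f.location]
        for part in parts:
            start, end = int(part.start), int(part.end)
            if 0 <= start < end <= length:
                feats.append((label, start, end, strand))
    return tuple(feats)


def read_reference(
    path: str | Path,
    format: str | None = None,
    circular: bool | None = None,
) -> ReferenceRecord:
    """Read a designed reference from GenBank or FASTA.

    Topology is taken from the GenBank LOCUS line; FASTA defaults to
    linear unless ``circular=True`` is forced.
    """
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    if format not in {"genbank", "fasta"}:
        raise ValueError(f"unknown reference format {format!r}")
    try:
        record = next(SeqIO.parse(str(path), format))
    except (FileNotFoundError, PermissionError) as exc:
        raise InputError(f"cannot read reference file {path}") from exc
    except (StopIteration, ValueError) as exc:
        raise InputError(f"no parseable {format} record in {path}") from exc
    seq = _normalize_sequence(str(record.seq), str(path))
    if not seq:
        raise ValidationError(f"empty sequence in {path}")
    if circular is None:
        circular = (
            format == "genbank"
            and record.annotations.get("topology", "linear") == "circular"
        )
    features = _features_from_seqrecord(record, len(seq)) if format == "genbank" else ()
    return ReferenceRecord(
        id=record.id, sequence=seq, circular=circular, features=features
    )


def read_references(paths: Iterable[str | Path], **kwargs) -> dict[str, ReferenceRecord]:
    """Read several references, keyed by record id."""
    refs: dict[str, ReferenceRecord] = {}
    for p in paths:
        rec = read_reference(p, **kwargs)
        if rec.id in refs:
            raise ValidationError(f"duplicate reference id {rec.id!r}")
        refs[rec.id] = rec
    return refs


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ("barcode", "sample", "reference")


def parse_sample_sheet(
    path: str | Path,
    references: dict[str, ReferenceRecord] | None = None,
) -> list[SampleSheetEntry]:
    """Parse a CSV sample sheet (columns barcode, sample, reference).

    Extra columns are ignored; row order is preserved. Duplicate barcodes,
    or reference ids absent from ``references`` (when given), raise
    :class:`ValidationError`.
    """
    path = Path(path)
    try:
        with open(path, newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle)
            if reader.fieldnames is None:
                raise ValidationError(f"sample sheet {path} is empty")
            missing = [c for c in _SHEET_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise ValidationError(
                    f"sample sheet {path} lacks column(s): {', '.join(missing)}"
                )
            entries = [
                SampleSheetEntry(
                    barcode=row["barcode"].strip(),
                    sample_name=row["sample"].strip(),
                    reference_id=row["reference"].strip(),
                )
                for row in reader
            ]
    except (FileNotFoundError, PermissionError) as exc:
        raise InputError(f"cannot read sample sheet {path}") from exc
    seen: dict[str, int] = {}
    dupes = []
    for e in entries:
        if e.barcode in seen:
            dupes.append(e.barcode)
        seen[e.barcode] = 1
    if dupes:
        raise ValidationError(f"duplicate barcode(s) in sample sheet: {sorted(set(dupes))}")
    if references is not None:
        unknown = sorted({e.reference_id for e in entries} - set(references))
        if unknown:
            raise ValidationError(f"sample sheet references unknown reference id(s): {unknown}")
    return entries


def write_sample_sheet(entries: Sequence[SampleSheetEntry], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_SHEET_COLUMNS)
        for e in entries:
            writer.writerow([e.barcode, e.sample_name, e.reference_id])


# ---------------------------------------------------------------------------
# Reads (FASTQ)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[Read]:
    """Read a FASTQ file into :class:`Read` objects."""
    try:
        records = list(SeqIO.parse(str(path), "fastq"))
    except (FileNotFoundError, PermissionError) as exc:
        raise InputError(f"cannot read FASTQ file {path}") from exc
    except ValueError as exc:
        raise InputError(f"malformed FASTQ in {path}: {exc}") from exc
    return [
        Read(
            id=r.id,
            sequence=str(r.seq).upper(),
            qualities=tuple(r.letter_annotations["phred_quality"]),
        )
        for r in records
    ]


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    with open(path, "w", encoding="ascii") as handle:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.qualities)
            handle.write(f"@{r.id}\n{r.sequence}\n+\n{quals}\n")


# ---------------------------------------------------------------------------
# Alignments (SAM)
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path) -> list[ReadAlignment]:
    """Parse a SAM file into :class:`ReadAlignment` records.

    Secondary alignments (flag 0x100) are dropped; supplementary records
    (0x800) are retained and linked to their primary by read id; unmapped
    reads (0x4) become placeholders retaining the read length.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cannot read SAM file {path}")
    # htslib silently downgrades records with an undeclared RNAME to
    # unmapped; pre-scan the text so they are a hard format error instead
    declared: set[str] = set()
    with open(path, encoding="ascii", errors="replace") as handle:
        for line in handle:
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for field in line.rstrip("\n").split("\t")[1:]:
                        if field.startswith("SN:"):
                            declared.add(field[3:])
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3 and fields[2] not in ("*", "") and fields[2] not in declared:
                raise InputError(
                    f"record {fields[0]!r} in {path} refers to reference "
                    f"{fields[2]!r} absent from the header"
                )
    out: list[ReadAlignment] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
            for seg in sam.fetch(until_eof=True):
                if seg.is_secondary:
                    continue
                if seg.is_unmapped:
                    seq = seg.query_sequence or ""
                    out.append(
                        ReadAlignment(
                            read_id=seg.query_name,
                            reference_id="",
                            start=-1,
                            cigar=(),
                            strand="forward",
                            mapped=False,
                            read_length=len(seq),
                            read_sequence=seq or None,
                        )
                    )
                    continue
                if seg.cigartuples is None:
                    raise InputError(
                        f"mapped record {seg.query_name!r} in {path} lacks a CIGAR"
                    )
                cigar = tuple((CIGAR_OPS[op], n) for op, n in seg.cigartuples)
                read_len = sum(n for op, n in cigar if op in QUERY_OPS or op == "H")
                seq = seg.query_sequence
                if seq is not None:
                    soft = sum(n for op, n in cigar if op in QUERY_OPS)
                    if len(seq) != soft:
                        raise InputError(
                            f"record {seg.query_name!r} in {path}: sequence length "
                            f"{len(seq)} does not match CIGAR ({soft})"
                        )
                out.append(
                    ReadAlignment(
                        read_id=seg.query_name,
                        reference_id=seg.reference_name,
                        start=seg.reference_start,
                        cigar=cigar,
                        strand="reverse" if seg.is_reverse else "forward",
                        mapped=True,
                        read_length=read_len,
                        is_supplementary=seg.is_supplementary,
                        read_sequence=seq,
                    )
                )
    except ValueError as exc:
        raise InputError(f"malformed SAM in {path}: {exc}") from exc
    return out


def group_by_read(alignments: Iterable[ReadAlignment]) -> dict[str, list[ReadAlignment]]:
    """Group primary + supplementary records per read id, input order preserved."""
    groups: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        groups.setdefault(aln.read_id, []).append(aln)
    return groups
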