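"""Structural-error evidence from alignments.

Coverage over a (possibly circular) reference, maximal zero-coverage
sections, the per-read longest unaligned interval, and the fraction of
reads carrying a large unaligned segment. On circular references all
positions are taken modulo the reference length, so alignment spans
extending past the sequence end wrap to position 0.

Deleted reference positions (CIGAR D) count as covered: a read spanning
a small deletion still attests that the region is present once. Only
true structural absence — no spanning reads at all — produces
zero-coverage sections, which is what makes them the signature of
construct deletions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import (
    ALIGNED_OPS,
    REF_OPS,
    ReadAlignment,
    ReferenceRecord,
    ValidationError,
)

DEFAULT_MIN_INSERT_LENGTH = 50


@dataclass(frozen=True)
class CoverageProfile:
    """Per-position read depth over one reference."""

    reference_id: str
    depth: np.ndarray
    circular: bool

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    @property
    def length(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class ZeroCoverageSection:
    """A maximal run of zero-depth reference positions (may wrap the origin)."""

    start: int
    end: int  # exclusive; ≤ start when the section wraps the origin
    length: int
    wraps_origin: bool = False


def compute_coverage(
    alignments: Iterable[ReadAlignment], reference: ReferenceRecord
) -> CoverageProfile:
    """Depth[p] = number of alignment records whose reference-consuming
    span (M/=/X/D) covers position p."""
    n = reference.length
    depth = np.zeros(n, dtype=np.int64)
    for aln in alignments:
        if not aln.mapped:
            continue
        if aln.reference_id != reference.id:
            raise ValidationError(
                f"alignment of {aln.read_id!r} refers to {aln.reference_id!r}, "
                f"not {reference.id!r}"
            )
        span = aln.reference_span
        if not reference.circular and aln.start + span > n:
            raise ValidationError(
                f"alignment of {aln.read_id!r} extends past the end of the "
                f"linear reference {reference.id!r}"
            )
        pos = aln.start
        for op, length in aln.cigar:
            if op in REF_OPS:
                lo = pos % n
                hi = lo + length
                if hi <= n:
                    depth[lo:hi] += 1
                else:  # wrap on circular references
                    depth[lo:n] += 1
                    rem = hi - n
                    full, part = divmod(rem, n)
                    if full:
                        depth += full
                    depth[0:part] += 1
                pos += length
    return CoverageProfile(reference_id=reference.id, depth=depth, circular=reference.circular)


def zero_coverage_sections(profile: CoverageProfile) -> list[ZeroCoverageSection]:
    """Maximal runs of zero depth, sorted by start; on circular references
    a run touching both ends merges into one origin-wrapping section."""
    depth = profile.depth
    n = len(depth)
    if n == 0:
        return []
    zero = depth == 0
    if zero.all():
        return [ZeroCoverageSection(0, n, n, wraps_origin=profile.circular)]
    # run boundaries on the linear layout
    edges = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts = [0] if zero[0] else []
    starts += [int(e) + 1 for e in edges if not zero[e]]
    ends = [int(e) + 1 for e in edges if zero[e]]
    if zero[-1]:
        ends.append(n)
    sections = [
        ZeroCoverageSection(s, e, e - s) for s, e in zip(sorted(starts), sorted(ends))
    ]
    if profile.circular and len(sections) >= 2 and zero[0] and zero[-1]:
        first, last = sections[0], sections[-1]
        merged = ZeroCoverageSection(
            start=last.start,
            end=first.end,
            length=first.length + last.length,
            wraps_origin=True,
        )
        sections = sections[1:-1] + [merged]
        sections.sort(key=lambda s: s.start)
    return sections


def _read_coverage_mask(group: Sequence[ReadAlignment]) -> np.ndarray | None:
    """Boolean mask over original-read positions covered by aligned ops
    (M/=/X) in any record of the group; None for an unmapped-only group."""
    mapped = [a for a in group if a.mapped]
    if not mapped:
        return None
    read_length = group[0].read_length
    for a in group:
        if a.read_length != read_length:
            raise ValidationError(
                f"inconsistent read_length within group {group[0].read_id!r}"
            )
    mask = np.zeros(read_length, dtype=bool)
    for aln in mapped:
        qpos = 0
        for op, length in aln.cigar:
            if op in ALIGNED_OPS:
                if aln.strand == "reverse":
                    # CIGAR is in reference orientation; map back onto the
                    # original read coordinates
                    mask[read_length - qpos - length : read_length - qpos] = True
                else:
                    mask[qpos : qpos + length] = True
            if op in ("M", "I", "S", "=", "X", "H"):
                qpos += length
    return mask


def longest_unaligned_interval(group: Sequence[ReadAlignment]) -> int:
    """Longest maximal read interval not aligned to the reference by any
    record (primary + supplementaries merged); read_length for an
    unmapped read."""
    mask = _read_coverage_mask(group)
    if mask is None:
        return group[0].read_length
    best = run = 0
    for covered in mask:
        if covered:
            run = 0
        else:
            run += 1
            if run > best:
                best = run
    return best


def insert_read_fraction(
    read_groups: Mapping[str, Sequence[ReadAlignment]],
    min_insert_length: int = DEFAULT_MIN_INSERT_LENGTH,
) -> float:
    """Fraction of reads whose longest unaligned interval reaches
    ``min_insert_length``; unmapped reads count in both numerator
    (interval = read length) and denominator."""
    if not read_groups:
        raise ValidationError("insert fraction undefined for an empty read set")
    n_hit = sum(
        1
        for group in read_groups.values()
        if longest_unaligned_interval(group) >= min_insert_length
    )
    return n_hit / len(read_groups)


def write_bedgraph(profile: CoverageProfile, path) -> None:
    """Export coverage as BedGraph text (0-based half-open)."""
    depth = profile.depth
    with open(path, "w", encoding="ascii") as handle:
        if len(depth) == 0:
            return
        start = 0
        for pos in range(1, len(depth) + 1):
            if pos == len(depth) or depth[pos] != depth[start]:
                handle.write(
                    f"{profile.reference_id}\t{start}\t{pos}\t{int(depth[start])}\n"
                )
                start = pos
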