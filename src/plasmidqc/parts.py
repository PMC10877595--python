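"""Part mapping: locate constituent DNA parts on an assembled plasmid.

Given the parts a construct was assembled from (e.g. by Golden Gate
cloning) and an assembled or consensus sequence, this module reports
where each part lands, in which orientation and at what identity —
enough to diagnose part mix-ups, recombination events and overhang
misannealing from the part order alone.

Candidate loci are found by exact k-mer seeding and scored by unit-cost
edit alignment (edlib); identity is matches over aligned columns.
Circular targets are searched on the doubled sequence, with hits longer
than the target rejected and coordinates reported modulo the target
length.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Sequence

import edlib

from .io import ReferenceRecord, ValidationError

DEFAULT_SEED_K = 15
DEFAULT_MIN_IDENTITY = 0.8
DEFAULT_MIN_PART_COVERAGE = 0.5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PartHit:
    """One placement of a part on the target."""

    part_id: str
    target_start: int
    target_end: int  # half-open; ≤ target_start only when wraps_origin
    strand: str  # "forward" | "reverse"
    identity: float
    part_coverage: float
    wraps_origin: bool = False

    def span_length(self, target_length: int) -> int:
        if self.wraps_origin:
            return target_length - self.target_start + self.target_end
        return self.target_end - self.target_start


@dataclass(frozen=True)
class PartMapReport:
    hits: tuple[PartHit, ...]
    part_order: tuple[str, ...]
    uncovered_intervals: tuple[tuple[int, int], ...]
    missing_parts: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "hits": [
                {
                    "part_id": h.part_id,
                    "target_start": h.target_start,
                    "target_end": h.target_end,
                    "strand": h.strand,
                    "identity": round(h.identity, 6),
                    "part_coverage": round(h.part_coverage, 6),
                    "wraps_origin": h.wraps_origin,
                }
                for h in self.hits
            ],
            "part_order": list(self.part_order),
            "uncovered_intervals": [list(t) for t in self.uncovered_intervals],
            "missing_parts": list(self.missing_parts),
        }


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _score_alignment(cigar: str, part_length: int) -> tuple[float, float, int, int]:
    """Identity, part coverage and target-side trim offsets after trimming
    unaligned (query-only) alignment ends."""
    ops = _parse_cigar(cigar)
    # trim leading/trailing query-only runs: those part bases are unaligned
    lead_trim = 0
    while ops and ops[0][1] == "I":
        ops.pop(0)
    trail_trim = 0
    while ops and ops[-1][1] == "I":
        ops.pop()
    # also trim terminal target-only runs so hit coordinates stay tight
    lead_t = 0
    while ops and ops[0][1] == "D":
        lead_t += ops.pop(0)[0]
    trail_t = 0
    while ops and ops[-1][1] == "D":
        trail_t += ops.pop()[0]
    if not ops:
        return 0.0, 0.0, 0, 0
    columns = sum(n for n, _ in ops)
    matches = sum(n for n, op in ops if op == "=")
    query_aligned = sum(n for n, op in ops if op in ("=", "X", "I", "M"))
    return matches / columns, query_aligned / part_length, lead_t, trail_t


def _seed_windows(query: str, target: str, seed_k: int) -> list[tuple[int, int]]:
    """Candidate target windows from clustered exact k-mer match diagonals."""
    index: dict[str, list[int]] = {}
    for i in range(len(target) - seed_k + 1):
        index.setdefault(target[i : i + seed_k], []).append(i)
    diagonals: list[int] = []
    step = max(1, seed_k // 3)
    for qi in range(0, len(query) - seed_k + 1, step):
        for ti in index.get(query[qi : qi + seed_k], ()):
            diagonals.append(ti - qi)
    if not diagonals:
        return []
    diagonals.sort()
    pad = max(30, len(query) // 4)
    clusters: list[tuple[int, int]] = []
    lo = hi = diagonals[0]
    for d in diagonals[1:]:
        if d - hi <= pad:
            hi = d
        else:
            clusters.append((lo, hi))
            lo = hi = d
    clusters.append((lo, hi))
    windows = []
    for lo, hi in clusters:
        wstart = max(0, lo - pad)
        wend = min(len(target), hi + len(query) + pad)
        windows.append((wstart, wend))
    return windows


def locate_part(
    part: ReferenceRecord,
    target: str,
    circular: bool = False,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_k: int = DEFAULT_SEED_K,
    min_part_coverage: float = DEFAULT_MIN_PART_COVERAGE,
) -> list[PartHit]:
    """All non-overlapping placements of ``part`` on ``target``, best first.

    Both strands are searched. Hits require identity ≥ ``min_identity``
    and part coverage ≥ ``min_part_coverage``.
    """
    if len(part.sequence) < seed_k:
        raise ValidationError(
            f"part {part.id!r} ({len(part.sequence)} nt) is shorter than seed_k={seed_k}"
        )
    if not (0 < min_identity <= 1):
        raise ValidationError("min_identity must be in (0, 1]")
    target = target.upper()
    n = len(target)
    search = target + target if circular else target

    candidates: list[PartHit] = []
    for strand, query in (
        ("forward", part.sequence),
        ("reverse", reverse_complement(part.sequence)),
    ):
        for wstart, wend in _seed_windows(query, search, seed_k):
            res = edlib.align(query, search[wstart:wend], mode="HW", task="path")
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            loc_s, loc_e = res["locations"][0]
            identity, coverage, lead_t, trail_t = _score_alignment(
                res["cigar"], len(part.sequence)
            )
            s = wstart + loc_s + lead_t
            e = wstart + loc_e + 1 - trail_t
            if e - s > n:  # longer than the whole circle: spurious doubled hit
                continue
            if identity < min_identity or coverage < min_part_coverage:
                continue
            wraps = False
            if circular:
                if s >= n:
                    s, e = s - n, e - n
                if e > n:
                    e -= n
                    wraps = True
            candidates.append(
                PartHit(
                    part_id=part.id,
                    target_start=s,
                    target_end=e,
                    strand=strand,
                    identity=identity,
                    part_coverage=coverage,
                    wraps_origin=wraps,
                )
            )

    # best-first selection of non-overlapping hits
    candidates.sort(
        key=lambda h: (-h.identity * h.part_coverage, h.target_start, h.strand)
    )

    def positions(h: PartHit) -> set[int]:
        if h.wraps_origin:
            return set(range(h.target_start, n)) | set(range(0, h.target_end))
        return set(range(h.target_start, h.target_end))

    chosen: list[PartHit] = []
    occupied: set[int] = set()
    for hit in candidates:
        pos = positions(hit)
        if len(pos & occupied) > 0.5 * len(pos):
            continue
        # drop exact duplicates from overlapping seed windows
        if any(
            c.target_start == hit.target_start
            and c.target_end == hit.target_end
            and c.strand == hit.strand
            for c in chosen
        ):
            continue
        chosen.append(hit)
        occupied |= pos
    return chosen


def build_part_map(
    parts: Sequence[ReferenceRecord],
    target: str,
    circular: bool = False,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_k: int = DEFAULT_SEED_K,
    min_part_coverage: float = DEFAULT_MIN_PART_COVERAGE,
) -> PartMapReport:
    """Map every part onto the target and summarize order, gaps and
    missing parts."""
    if not parts:
        raise ValidationError("at least one part is required")
    n = len(target)
    hits: list[PartHit] = []
    missing: list[str] = []
    for part in parts:
        part_hits = locate_part(
            part,
            target,
            circular=circular,
            min_identity=min_identity,
            seed_k=seed_k,
            min_part_coverage=min_part_coverage,
        )
        if part_hits:
            hits.extend(part_hits)
        else:
            missing.append(part.id)

    ordered = sorted(hits, key=lambda h: (h.target_start, h.part_id))
    if circular and ordered:
        # deterministic circular order: start at the lexicographically
        # smallest part id's first hit
        anchor_id = min(h.part_id for h in ordered)
        k = next(i for i, h in enumerate(ordered) if h.part_id == anchor_id)
        ordered = ordered[k:] + ordered[:k]
    part_order = tuple(h.part_id for h in ordered)

    covered = set()
    for h in hits:
        if h.wraps_origin:
            covered |= set(range(h.target_start, n)) | set(range(0, h.target_end))
        else:
            covered |= set(range(h.target_start, h.target_end))
    uncovered: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if i not in covered:
            j = i
            while j < n and j not in covered:
                j += 1
            uncovered.append((i, j))
            i = j
        else:
            i += 1
    if circular and len(uncovered) >= 2:
        first, last = uncovered[0], uncovered[-1]
        if first[0] == 0 and last[1] == n:
            uncovered = uncovered[1:-1] + [(last[0], first[1])]

    return PartMapReport(
        hits=tuple(sorted(hits, key=lambda h: (h.target_start, h.part_id))),
        part_order=part_order,
        uncovered_intervals=tuple(uncovered),
        missing_parts=tuple(missing),
    )


def write_hits_table(report: PartMapReport, path) -> None:
    """Tab-separated hits table: part_id, start, end, strand, identity,
    part_coverage."""
    with open(path, "w", encoding="ascii") as handle:
        handle.write("part_id\ttarget_start\ttarget_end\tstrand\tidentity\tpart_coverage\n")
        for h in report.hits:
            handle.write(
                f"{h.part_id}\t{h.target_start}\t{h.target_end}\t{h.strand}\t"
                f"{h.identity:.4f}\t{h.part_coverage:.4f}\n"
            )


def write_part_map_json(report: PartMapReport, path) -> None:
    with open(path, "w", encoding="ascii") as handle:
        json.dump(report.to_dict(), handle, indent=2)
        handle.write("\n")
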