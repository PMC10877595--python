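"""Synthetic sequencing runs with known truth.

Emulates a rapid-barcoding nanopore run on circular plasmids: random
circular fragmentation (uniform start positions), lognormally
distributed read lengths, per-base substitution/insertion/deletion
errors with homopolymer-boosted deletions, and scripted construct
defects (SNV, interval deletion, insertion, replacement, mixtures).
For each barcode it writes FASTQ reads, a truth SAM against the
*designed reference*, a truth JSON, and a matching sample sheet — so
the whole analysis pipeline is testable without an external aligner.

Reads are simulated against the (edited) template; truth alignments
are then lifted into reference coordinates through the edit. Small
edits (< ``SV_MIN_LENGTH``) appear inside the CIGAR as I/D ops or as
mismatching M columns, the way an aligner reports small indels and
substitutions. Large edits split the read into soft-clipped primary +
supplementary records, the way long-read aligners report structural
breakpoints — which is what makes zero-coverage sections the
observable signature of construct deletions, and long unaligned read
segments the signature of insertions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    Read,
    ReferenceRecord,
    SampleSheetEntry,
    ValidationError,
    write_fastq,
    write_sample_sheet,
)
from .parts import reverse_complement

#: Edits at least this long are represented structurally (split/clipped
#: records) rather than inside the CIGAR.
SV_MIN_LENGTH = 50

#: Aligned blocks spanning fewer reference bases than this are treated as
#: unmappable and folded into soft clips (a real aligner would not anchor
#: them).
MIN_BLOCK = 30

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Scenario scripting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error rates.

    ``homopolymer_del_boost`` multiplies the deletion probability by
    boost^(run−1) inside a homopolymer run of length ``run`` — the
    dominant systematic nanopore error mode.
    """

    p_sub: float = 0.03
    p_ins: float = 0.01
    p_del: float = 0.02
    homopolymer_del_boost: float = 1.5
    quality_mean: float = 12.0

    def __post_init__(self) -> None:
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not (0 <= p < 0.5):
                raise ValidationError("error probabilities must be in [0, 0.5)")
        if self.homopolymer_del_boost < 1:
            raise ValidationError("homopolymer_del_boost must be ≥ 1")


ZERO_ERROR = ErrorModel(p_sub=0.0, p_ins=0.0, p_del=0.0, homopolymer_del_boost=1.0)


@dataclass(frozen=True)
class Edit:
    """A scripted construct defect.

    kind ∈ {none, snv, delete, insert, replace}; coordinates are on the
    designed reference, 0-based half-open.
    """

    kind: str = "none"
    start: int = 0
    end: int = 0
    seq: str = ""

    @staticmethod
    def none() -> "Edit":
        return Edit("none")

    @staticmethod
    def snv(pos: int, alt: str) -> "Edit":
        return Edit("snv", pos, pos + 1, alt)

    @staticmethod
    def delete(start: int, end: int) -> "Edit":
        return Edit("delete", start, end)

    @staticmethod
    def insert(pos: int, seq: str) -> "Edit":
        return Edit("insert", pos, pos, seq)

    @staticmethod
    def replace(start: int, end: int, seq: str) -> "Edit":
        return Edit("replace", start, end, seq)

    def describe(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind != "none":
            d.update(start=self.start, end=self.end)
        if self.seq:
            d["seq"] = self.seq
        return d


@dataclass(frozen=True)
class Scenario:
    """A simulator script: one construct defect plus an error model.

    ``mixture``, when non-empty, overrides ``template_edit`` with a
    weighted set of sub-edits (a polyclonal sample).
    """

    name: str
    template_edit: Edit = field(default_factory=Edit.none)
    mixture: tuple[tuple[Edit, float], ...] = ()
    n_reads: int = 80
    read_length_log_mean: float = math.log(2000.0)
    read_length_log_sd: float = 0.35
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def components(self) -> tuple[tuple[Edit, float], ...]:
        if self.mixture:
            total = sum(w for _, w in self.mixture)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValidationError("mixture weights must sum to 1")
            return self.mixture
        return ((self.template_edit, 1.0),)


@dataclass(frozen=True)
class Template:
    """An edited copy of the reference with its coordinate map.

    ``segments`` are collinear blocks ``(t_lo, t_hi, r_lo)``: template
    interval [t_lo, t_hi) maps to the reference starting at r_lo; r_lo
    is None for inserted (unaligned) material.
    """

    sequence: str
    segments: tuple[tuple[int, int, int | None], ...]
    edit: Edit
    weight: float = 1.0

    @property
    def length(self) -> int:
        return len(self.sequence)


def _build_template(reference: ReferenceRecord, edit: Edit, weight: float) -> Template:
    seq = reference.sequence
    n = len(seq)
    k = edit.kind
    if k != "none" and not (0 <= edit.start <= edit.end <= n):
        raise ValidationError(f"edit {edit} out of bounds for reference of length {n}")
    if k == "none":
        return Template(seq, ((0, n, 0),), edit, weight)
    if k == "snv":
        if len(edit.seq) != 1 or edit.seq == seq[edit.start]:
            raise ValidationError(f"invalid SNV alt {edit.seq!r} at {edit.start}")
        t = seq[: edit.start] + edit.seq + seq[edit.start + 1 :]
        return Template(t, ((0, n, 0),), edit, weight)
    if k == "delete":
        if edit.end <= edit.start:
            raise ValidationError("deletion interval is empty")
        t = seq[: edit.start] + seq[edit.end :]
        return Template(t, ((0, edit.start, 0), (edit.start, len(t), edit.end)), edit, weight)
    if k == "insert":
        li = len(edit.seq)
        if li == 0:
            raise ValidationError("insertion sequence is empty")
        t = seq[: edit.start] + edit.seq + seq[edit.start :]
        segs = (
            (0, edit.start, 0),
            (edit.start, edit.start + li, None),
            (edit.start + li, len(t), edit.start),
        )
        return Template(t, segs, edit, weight)
    if k == "replace":
        li = len(edit.seq)
        if li == 0 or edit.end <= edit.start:
            raise ValidationError("replacement needs a non-empty interval and sequence")
        t = seq[: edit.start] + edit.seq + seq[edit.end :]
        if li == edit.end - edit.start and li < SV_MIN_LENGTH:
            # small same-length replacement: collinear, surfaces as mismatches
            return Template(t, ((0, len(t), 0),), edit, weight)
        segs = (
            (0, edit.start, 0),
            (edit.start, edit.start + li, None),
            (edit.start + li, len(t), edit.end),
        )
        return Template(t, segs, edit, weight)
    raise ValidationError(f"unknown edit kind {k!r}")


def apply_scenario(reference: ReferenceRecord, scenario: Scenario) -> tuple[list[Template], dict]:
    """Edited template(s) plus a truth record of every edit in reference
    coordinates."""
    templates = [
        _build_template(reference, edit, weight) for edit, weight in scenario.components()
    ]
    truth = {
        "scenario": scenario.name,
        "reference_id": reference.id,
        "edits": [{"weight": t.weight, **t.edit.describe()} for t in templates],
    }
    return templates, truth


# ---------------------------------------------------------------------------
# Read simulation (template space)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedRead:
    """One read with its truth placement in *template* space."""

    read: Read  # FASTQ (read) orientation
    template_index: int
    tstart: int  # template start; the alignment may wrap on circles
    cigar: tuple[tuple[str, int], ...]  # template-space truth: M/I/D only
    strand: str  # forward | reverse
    aligned_sequence: str  # reference-orientation sequence


def _homopolymer_run_lengths(seq: str) -> np.ndarray:
    """Length of the maximal homopolymer run containing each position."""
    n = len(seq)
    runs = np.ones(n, dtype=np.int32)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        runs[i:j] = j - i
        i = j
    return runs


def _compact(ops: Sequence[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return tuple(out)


def _simulate_one(
    template: str,
    runs: np.ndarray,
    circular: bool,
    scenario: Scenario,
    rng: np.random.Generator,
    read_id: str,
    template_index: int,
) -> SimulatedRead:
    n = len(template)
    em = scenario.error_model
    length = int(
        np.clip(
            round(rng.lognormal(scenario.read_length_log_mean, scenario.read_length_log_sd)),
            min(200, n),
            n,
        )
    )
    if circular:
        start = int(rng.integers(0, n))
        fragment = (template + template)[start : start + length]
        frag_runs = np.concatenate([runs, runs])[start : start + length]
    else:
        start = int(rng.integers(0, n - length + 1))
        fragment = template[start : start + length]
        frag_runs = runs[start : start + length]
    bases: list[str] = []
    ops: list[tuple[str, int]] = []
    for j, base in enumerate(fragment):
        run = int(frag_runs[j])
        p_del_eff = min(0.499, em.p_del * em.homopolymer_del_boost ** (run - 1))
        if em.p_del > 0 and rng.random() < p_del_eff:
            ops.append(("D", 1))
            continue
        if em.p_sub > 0 and rng.random() < em.p_sub:
            base = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4] if base in BASES else "A"
        bases.append(base)
        ops.append(("M", 1))
        if em.p_ins > 0 and rng.random() < em.p_ins:
            bases.append(BASES[int(rng.integers(0, 4))])
            ops.append(("I", 1))
    aligned_seq = "".join(bases)
    strand = "forward" if rng.random() < 0.5 else "reverse"
    quals = np.clip(
        np.rint(rng.normal(em.quality_mean, 3.0, size=len(aligned_seq))), 2, 41
    ).astype(int)
    if strand == "reverse":
        read_seq = reverse_complement(aligned_seq)
        read_quals = tuple(int(q) for q in quals[::-1])
    else:
        read_seq = aligned_seq
        read_quals = tuple(int(q) for q in quals)
    return SimulatedRead(
        read=Read(id=read_id, sequence=read_seq, qualities=read_quals),
        template_index=template_index,
        tstart=start,
        cigar=_compact(ops),
        strand=strand,
        aligned_sequence=aligned_seq,
    )


def simulate_reads(
    template: str,
    circular: bool,
    scenario: Scenario,
    rng: np.random.Generator | None = None,
    template_index: int = 0,
    read_prefix: str = "read",
) -> list[SimulatedRead]:
    """Simulate ``scenario.n_reads`` reads from one template.

    Start positions are uniform on the circle (or over valid linear
    starts); lengths lognormal, clipped to [200, template length];
    errors per :class:`ErrorModel` with homopolymer-boosted deletion.
    Fully reproducible from the scenario seed.
    """
    if scenario.n_reads < 1:
        raise ValidationError("n_reads must be ≥ 1")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    runs = _homopolymer_run_lengths(template)
    return [
        _simulate_one(
            template, runs, circular, scenario, rng, f"{read_prefix}_{i:05d}", template_index
        )
        for i in range(scenario.n_reads)
    ]


# ---------------------------------------------------------------------------
# Lift-over: template-space truth -> reference-space SAM records
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    ref_start: int | None  # None for unaligned (inserted) material
    q_lo: int
    q_hi: int
    ops: list[tuple[str, int]]

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in ("M", "D"))

    @property
    def query_span(self) -> int:
        return sum(n for op, n in self.ops if op in ("M", "I"))


def _lift_blocks(sim: SimulatedRead, template: Template) -> list[_Block]:
    """Split the template-space truth alignment at segment and origin
    boundaries into collinear blocks."""
    segs = template.segments
    lt = template.length
    blocks: list[_Block] = []
    cur: _Block | None = None
    cur_end = 0  # template coordinate (unwrapped) where cur's segment ends
    t_real = sim.tstart
    q = 0

    def open_block() -> None:
        nonlocal cur, cur_end
        t = t_real % lt
        base = t_real - t
        for lo, hi, r in segs:
            if lo <= t < hi:
                ref_start = None if r is None else r + (t - lo)
                cur = _Block(ref_start=ref_start, q_lo=q, q_hi=q, ops=[])
                cur_end = base + hi
                blocks.append(cur)
                return
        raise AssertionError("template position outside segment map")

    for op, length in sim.cigar:
        if op == "I":
            if cur is None:
                open_block()
            cur.ops.append(("I", length))
            q += length
            cur.q_hi = q
            continue
        remaining = length
        while remaining > 0:
            if cur is None:
                open_block()
            chunk = min(remaining, cur_end - t_real)
            cur.ops.append((op, chunk))
            t_real += chunk
            if op == "M":
                q += chunk
            cur.q_hi = q
            remaining -= chunk
            if t_real == cur_end:
                cur = None
    return blocks


@dataclass(frozen=True)
class TruthRecord:
    """One reference-space SAM record derived from a simulated read."""

    ref_start: int
    cigar: tuple[tuple[str, int], ...]  # includes soft clips
    is_supplementary: bool
    mapped: bool


def lift_to_reference(
    sim: SimulatedRead,
    template: Template,
    sv_min: int = SV_MIN_LENGTH,
    min_block: int = MIN_BLOCK,
) -> list[TruthRecord]:
    """Turn a template-space truth alignment into reference-space records.

    Adjacent collinear blocks separated by a small reference gap and/or
    a small run of unaligned read bases are joined with D/I ops; larger
    discontinuities split the read into soft-clipped records.
    """
    blocks = [
        b
        for b in _lift_blocks(sim, template)
        if b.ref_start is not None and b.ref_span >= min_block
    ]
    if not blocks:
        return [TruthRecord(ref_start=-1, cigar=(), is_supplementary=False, mapped=False)]

    # merge joinable neighbours
    groups: list[list[_Block]] = [[blocks[0]]]
    for blk in blocks[1:]:
        prev = groups[-1][-1]
        ref_gap = (
            blk.ref_start - (prev.ref_start + prev.ref_span)
            if prev.ref_start is not None and blk.ref_start is not None
            else None
        )
        q_gap = blk.q_lo - prev.q_hi
        if ref_gap is not None and 0 <= ref_gap < sv_min and 0 <= q_gap < sv_min:
            groups[-1].append(blk)
        else:
            groups.append([blk])

    total_len = len(sim.aligned_sequence)
    records: list[TruthRecord] = []
    for group in groups:
        ops: list[tuple[str, int]] = []
        for i, blk in enumerate(group):
            if i > 0:
                prev = group[i - 1]
                q_gap = blk.q_lo - prev.q_hi
                ref_gap = blk.ref_start - (prev.ref_start + prev.ref_span)
                if q_gap > 0:
                    ops.append(("I", q_gap))
                if ref_gap > 0:
                    ops.append(("D", ref_gap))
            ops.extend(blk.ops)
        q_lo, q_hi = group[0].q_lo, group[-1].q_hi
        ref_start = group[0].ref_start
        # fold terminal insertions into the clips; trim terminal deletions
        trimming = True
        while trimming and ops:
            trimming = False
            if ops and ops[0][0] == "I":
                q_lo += ops.pop(0)[1]
                trimming = True
            if ops and ops[0][0] == "D":
                ref_start += ops.pop(0)[1]
                trimming = True
            if ops and ops[-1][0] == "I":
                q_hi -= ops.pop()[1]
                trimming = True
            if ops and ops[-1][0] == "D":
                ops.pop()
                trimming = True
        if not ops:
            continue
        cigar: list[tuple[str, int]] = []
        if q_lo > 0:
            cigar.append(("S", q_lo))
        cigar.extend(ops)
        if total_len - q_hi > 0:
            cigar.append(("S", total_len - q_hi))
        records.append(
            TruthRecord(
                ref_start=ref_start,
                cigar=_compact(cigar),
                is_supplementary=False,
                mapped=True,
            )
        )
    if not records:
        return [TruthRecord(ref_start=-1, cigar=(), is_supplementary=False, mapped=False)]
    # longest aligned record is primary
    records.sort(
        key=lambda r: -sum(n for op, n in r.cigar if op in ("M", "=", "X"))
    )
    out = [records[0]]
    for r in records[1:]:
        out.append(TruthRecord(r.ref_start, r.cigar, True, True))
    return out


# ---------------------------------------------------------------------------
# Run emission
# ---------------------------------------------------------------------------

def _cigar_string(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def _sam_lines(
    reference: ReferenceRecord, sims: Sequence[SimulatedRead], templates: Sequence[Template]
) -> list[str]:
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{reference.id}\tLN:{reference.length}",
        "@PG\tID:plasmidqc-sim\tPN:plasmidqc-sim",
    ]
    for sim in sims:
        quals = sim.read.qualities
        if sim.strand == "reverse":
            aligned_quals = quals[::-1]
        else:
            aligned_quals = quals
        qual_str = "".join(chr(q + 33) for q in aligned_quals)
        records = lift_to_reference(sim, templates[sim.template_index])
        for rec in records:
            if not rec.mapped:
                lines.append(
                    "\t".join(
                        [
                            sim.read.id,
                            "4",
                            "*",
                            "0",
                            "0",
                            "*",
                            "*",
                            "0",
                            "0",
                            sim.read.sequence,
                            "".join(chr(q + 33) for q in quals),
                        ]
                    )
                )
                continue
            flag = 0
            if sim.strand == "reverse":
                flag |= 16
            if rec.is_supplementary:
                flag |= 2048
            lines.append(
                "\t".join(
                    [
                        sim.read.id,
                        str(flag),
                        reference.id,
                        str(rec.ref_start + 1),
                        "60",
                        _cigar_string(rec.cigar),
                        "*",
                        "0",
                        "0",
                        sim.aligned_sequence,
                        qual_str,
                    ]
                )
            )
    return lines


def simulate_barcode(
    reference: ReferenceRecord, scenario: Scenario, rng: np.random.Generator
) -> tuple[list[SimulatedRead], list[Template], dict]:
    """Simulate one barcode's reads, honoring mixture weights."""
    templates, truth = apply_scenario(reference, scenario)
    weights = np.array([t.weight for t in templates], dtype=float)
    weights /= weights.sum()
    assignment = rng.choice(len(templates), size=scenario.n_reads, p=weights)
    run_arrays = [_homopolymer_run_lengths(t.sequence) for t in templates]
    sims = [
        _simulate_one(
            templates[ti].sequence,
            run_arrays[ti],
            reference.circular,
            scenario,
            rng,
            f"{scenario.name}_read_{i:05d}",
            int(ti),
        )
        for i, ti in enumerate(assignment)
    ]
    truth["read_templates"] = {s.read.id: s.template_index for s in sims}
    return sims, templates, truth


def emit_run(
    reference: ReferenceRecord,
    scenarios: dict[str, Scenario],
    out_dir: str | Path,
    seed: int = 0,
) -> dict[str, Path]:
    """Write per-barcode FASTQ + truth SAM, a truth JSON and a sample
    sheet; returns the paths keyed by role."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(set(scenarios)) != len(scenarios):
        raise ValidationError("barcodes must be unique")
    entries = []
    truth_all: dict[str, dict] = {}
    paths: dict[str, Path] = {}
    for index, (barcode, scenario) in enumerate(scenarios.items()):
        rng = np.random.default_rng([seed, scenario.seed, index])
        sims, templates, truth = simulate_barcode(reference, scenario, rng)
        fastq_path = out_dir / f"{barcode}.fastq"
        sam_path = out_dir / f"{barcode}.sam"
        write_fastq([s.read for s in sims], fastq_path)
        with open(sam_path, "w", encoding="ascii") as handle:
            handle.write("\n".join(_sam_lines(reference, sims, templates)) + "\n")
        entries.append(
            SampleSheetEntry(barcode=barcode, sample_name=scenario.name, reference_id=reference.id)
        )
        truth_all[barcode] = truth
        paths[f"{barcode}.fastq"] = fastq_path
        paths[f"{barcode}.sam"] = sam_path
    sheet_path = out_dir / "sample_sheet.csv"
    truth_path = out_dir / "truth.json"
    write_sample_sheet(entries, sheet_path)
    with open(truth_path, "w", encoding="ascii") as handle:
        json.dump(truth_all, handle, indent=2, sort_keys=True)
        handle.write("\n")
    paths["sample_sheet"] = sheet_path
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

def random_reference(
    length: int = 3000,
    seed: int = 0,
    circular: bool = True,
    ref_id: str = "plasmid_design",
    homopolymer_length: int = 6,
) -> ReferenceRecord:
    """A random plasmid-like reference with one planted homopolymer run
    (so homopolymer-context scenarios always have a locus to hit)."""
    rng = np.random.default_rng(seed)
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    if homopolymer_length:
        pos = int(0.9 * length)
        base = "A"
        # avoid accidentally extending the run with the neighbours
        left = "C" if seq[pos - 1] == base else seq[pos - 1]
        right = "G" if seq[pos + homopolymer_length] == base else seq[pos + homopolymer_length]
        seq = (
            seq[: pos - 1]
            + left
            + base * homopolymer_length
            + right
            + seq[pos + homopolymer_length + 1 :]
        )
    return ReferenceRecord(id=ref_id, sequence=seq, circular=circular)


def standard_scenarios(
    reference: ReferenceRecord,
    n_reads: int = 80,
    seed: int = 0,
    error_model: ErrorModel | None = None,
) -> dict[str, Scenario]:
    """The eight canonical validation scenarios, keyed by barcode.

    Covers: correct construct, point mutation, 500 nt deletion, 500 nt
    insertion, 500 nt part replacement, too few reads, a single
    homopolymer indel, and a 50:50 polyclonal mixture.
    """
    em = error_model or ErrorModel()
    rng = np.random.default_rng([seed, 7])
    L = reference.length
    seq = reference.sequence
    runs = _homopolymer_run_lengths(seq)

    def isolated_pos(target: int) -> int:
        for p in range(target, L - 1):
            if runs[p] == 1:
                return p
        return target

    snv_pos = isolated_pos(L // 4)
    snv_alt = BASES[(BASES.index(seq[snv_pos]) + 2) % 4]
    random500 = "".join(BASES[i] for i in rng.integers(0, 4, size=500))
    random500b = "".join(BASES[i] for i in rng.integers(0, 4, size=500))

    # the planted/longest homopolymer run
    hp_best = int(np.argmax(runs))
    hp_mid = hp_best + int(runs[hp_best]) // 2

    # the 50:50 mixture pools two distinct defective clones (e.g. two
    # different overhang-misannealing products in one well): each clone
    # carries its own large insertion, so the insert-majority rule fires
    # no matter which clone a read comes from. A mixture of a correct and
    # a point-variant clone would instead sit exactly at the variant
    # caller's 0.5 threshold and surface only as sub-threshold noise.
    mix_ins_a = "".join(BASES[i] for i in rng.integers(0, 4, size=500))
    mix_ins_b = "".join(BASES[i] for i in rng.integers(0, 4, size=500))

    common = dict(n_reads=n_reads, error_model=em)
    return {
        "barcode01": Scenario(name="ok", template_edit=Edit.none(), **common),
        "barcode02": Scenario(name="point_mutation", template_edit=Edit.snv(snv_pos, snv_alt), **common),
        "barcode03": Scenario(
            name="deletion_500",
            template_edit=Edit.delete(2 * L // 5, 2 * L // 5 + 500),
            **common,
        ),
        "barcode04": Scenario(
            name="insertion_500", template_edit=Edit.insert(3 * L // 5, random500), **common
        ),
        "barcode05": Scenario(
            name="part_replacement",
            template_edit=Edit.replace(7 * L // 10, 7 * L // 10 + 500, random500b),
            **common,
        ),
        "barcode06": Scenario(
            name="low_reads", template_edit=Edit.none(), n_reads=10, error_model=em
        ),
        "barcode07": Scenario(
            name="homopolymer_indel",
            template_edit=Edit.delete(hp_mid, hp_mid + 1),
            **common,
        ),
        "barcode08": Scenario(
            name="mixed_5050",
            mixture=(
                (Edit.insert(L // 10, mix_ins_a), 0.5),
                (Edit.insert(L // 2, mix_ins_b), 0.5),
            ),
            **common,
        ),
    }
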