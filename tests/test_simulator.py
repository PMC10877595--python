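"""The synthetic-run generator: error model, truth CIGARs, lift-over and
determinism."""

from __future__ import annotations

import json

import numpy as np
import pytest

from plasmidqc import (
    Edit,
    ErrorModel,
    ReferenceRecord,
    Scenario,
    ZERO_ERROR,
    apply_scenario,
    emit_run,
    lift_to_reference,
    random_reference,
    read_alignments,
    simulate_reads,
)
from plasmidqc.simulate import _homopolymer_run_lengths


def _scenario(name="s", edit=None, n_reads=50, em=None, seed=0, **kw):
    return Scenario(
        name=name,
        template_edit=edit or Edit.none(),
        n_reads=n_reads,
        error_model=em or ErrorModel(),
        seed=seed,
        **kw,
    )


class TestApplyScenario:
    def test_none_edit_is_identity(self, reference):
        templates, truth = apply_scenario(reference, _scenario())
        assert templates[0].sequence == reference.sequence
        assert truth["edits"][0]["kind"] == "none"

    def test_snv_differs_at_exactly_one_position(self, reference):
        alt = "T" if reference.sequence[100] != "T" else "G"
        (t,), _ = apply_scenario(reference, _scenario(edit=Edit.snv(100, alt)))
        diffs = [
            i for i, (a, b) in enumerate(zip(t.sequence, reference.sequence)) if a != b
        ]
        assert diffs == [100]

    def test_deletion_shortens_template(self, reference):
        (t,), _ = apply_scenario(reference, _scenario(edit=Edit.delete(2000, 2500)))
        assert t.length == reference.length - 500

    def test_out_of_bounds_edit_rejected(self, reference):
        from plasmidqc import ValidationError

        with pytest.raises(ValidationError):
            apply_scenario(reference, _scenario(edit=Edit.delete(2900, 3500)))


class TestSimulateReads:
    def test_zero_error_reads_are_exact_substrings(self, reference):
        sc = _scenario(em=ZERO_ERROR, n_reads=30)
        sims = simulate_reads(reference.sequence, True, sc)
        doubled = reference.sequence * 2
        for s in sims:
            assert s.cigar == (("M", len(s.aligned_sequence)),)
            assert s.aligned_sequence in doubled

    def test_same_seed_byte_identical_run(self, reference, scenarios, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        emit_run(reference, scenarios, a, seed=123)
        emit_run(reference, scenarios, b, seed=123)
        for f in sorted(a.iterdir()):
            assert f.read_bytes() == (b / f.name).read_bytes(), f.name

    def test_substitution_rate_matches_error_model(self, reference):
        em = ErrorModel(p_sub=0.05, p_ins=0.0, p_del=0.0, homopolymer_del_boost=1.0)
        sc = _scenario(em=em, n_reads=200, seed=3)
        sims = simulate_reads(reference.sequence, True, sc)
        doubled = reference.sequence * 2
        mism = total = 0
        for s in sims:
            frag = doubled[s.tstart : s.tstart + len(s.aligned_sequence)]
            mism += sum(1 for x, y in zip(frag, s.aligned_sequence) if x != y)
            total += len(frag)
        assert abs(mism / total - 0.05) < 0.01

    def test_truth_cigar_reconstructs_read(self, reference):
        """With indel errors only, replaying the truth CIGAR over the
        template reproduces each emitted read exactly."""
        em = ErrorModel(p_sub=0.0, p_ins=0.02, p_del=0.03)
        sc = _scenario(em=em, n_reads=50, seed=4)
        sims = simulate_reads(reference.sequence, True, sc)
        doubled = reference.sequence * 2
        for s in sims:
            rebuilt = []
            t, q = s.tstart, 0
            for op, n in s.cigar:
                if op == "M":
                    rebuilt.append(doubled[t : t + n])
                    t += n
                    q += n
                elif op == "D":
                    t += n
                elif op == "I":
                    rebuilt.append(s.aligned_sequence[q : q + n])
                    q += n
            assert "".join(rebuilt) == s.aligned_sequence

    def test_coverage_uniformity_on_clean_circle(self):
        ref = random_reference(length=2000, seed=9)
        sc = _scenario(em=ZERO_ERROR, n_reads=500, seed=5)
        sims = simulate_reads(ref.sequence, True, sc)
        depth = np.zeros(ref.length)
        for s in sims:
            span = sum(n for op, n in s.cigar if op in ("M", "D"))
            for p in range(s.tstart, s.tstart + span):
                depth[p % ref.length] += 1
        lam = depth.mean()
        assert np.abs(depth - lam).max() < 5 * np.sqrt(lam)

    def test_homopolymer_deletion_bias(self):
        # template rich in homopolymers
        rng = np.random.default_rng(0)
        template = "".join(
            "ACGT"[i] * int(rng.integers(1, 7)) for i in rng.integers(0, 4, size=2000)
        )
        em = ErrorModel(p_sub=0.0, p_ins=0.0, p_del=0.02, homopolymer_del_boost=2.0)
        sc = _scenario(em=em, n_reads=300, seed=6)
        sims = simulate_reads(template, True, sc)
        runs = np.concatenate([_homopolymer_run_lengths(template)] * 2)
        dels_in = dels_out = bases_in = bases_out = 0
        for s in sims:
            t = s.tstart
            for op, n in s.cigar:
                if op == "I":
                    continue
                for p in range(t, t + n):
                    inside = runs[p] >= 4
                    if op == "D":
                        dels_in += inside
                        dels_out += not inside
                    bases_in += inside
                    bases_out += not inside
                t += n
        assert dels_in / bases_in > dels_out / bases_out


class TestLiftOver:
    def test_deletion_leaves_no_read_over_the_interval(self, simulated_run):
        """Truth SAM for the deletion scenario has no record covering the
        deleted reference interval."""
        truth = json.loads((simulated_run["dir"] / "truth.json").read_text())
        edit = truth["barcode03"]["edits"][0]
        lo, hi = edit["start"], edit["end"]
        alns = read_alignments(simulated_run["paths"]["barcode03.sam"])
        for a in alns:
            if not a.mapped:
                continue
            # spans may wrap the origin; check the non-wrapping portion(s)
            n = simulated_run["reference"].length
            spans = []
            if a.end <= n:
                spans.append((a.start, a.end))
            else:
                spans.extend([(a.start, n), (0, a.end - n)])
            for s, e in spans:
                assert e <= lo or s >= hi, (a.read_id, s, e)

    def test_deletion_read_split_into_primary_and_supplementary(self, reference):
        sc = _scenario(edit=Edit.delete(1000, 1500), em=ZERO_ERROR, n_reads=1)
        templates, _ = apply_scenario(reference, sc)
        # a read straddling the breakpoint
        from plasmidqc.simulate import SimulatedRead
        from plasmidqc.io import Read

        seq = templates[0].sequence[500:1500]
        sim = SimulatedRead(
            read=Read("r", seq, (12,) * len(seq)),
            template_index=0,
            tstart=500,
            cigar=(("M", len(seq)),),
            strand="forward",
            aligned_sequence=seq,
        )
        records = lift_to_reference(sim, templates[0])
        assert len(records) == 2
        primary = records[0]
        supp = records[1]
        assert not primary.is_supplementary and supp.is_supplementary
        starts = sorted(r.ref_start for r in records)
        assert starts == [500, 1500]

    def test_small_deletion_becomes_cigar_d_op(self, reference):
        sc = _scenario(edit=Edit.delete(1000, 1003), em=ZERO_ERROR, n_reads=1)
        templates, _ = apply_scenario(reference, sc)
        from plasmidqc.simulate import SimulatedRead
        from plasmidqc.io import Read

        seq = templates[0].sequence[900:1100]
        sim = SimulatedRead(
            read=Read("r", seq, (12,) * len(seq)),
            template_index=0,
            tstart=900,
            cigar=(("M", len(seq)),),
            strand="forward",
            aligned_sequence=seq,
        )
        (record,) = lift_to_reference(sim, templates[0])
        assert ("D", 3) in record.cigar

    def test_insertion_reads_carry_long_unaligned_segment(self, simulated_run):
        from plasmidqc import group_by_read, longest_unaligned_interval

        alns = read_alignments(simulated_run["paths"]["barcode04.sam"])
        groups = group_by_read(alns)
        truth = json.loads((simulated_run["dir"] / "truth.json").read_text())
        pos = truth["barcode04"]["edits"][0]["start"]
        big = sum(
            1 for g in groups.values() if longest_unaligned_interval(g) >= 400
        )
        # most reads span the 500 nt insertion and carry its bases unaligned
        assert big / len(groups) > 0.4

    def test_mixture_truth_tags_cover_both_templates(self, simulated_run):
        truth = json.loads((simulated_run["dir"] / "truth.json").read_text())
        tags = truth["barcode08"]["read_templates"]
        assert set(tags.values()) == {0, 1}


class TestEmitRun:
    def test_outputs_consumable_by_io_layer(self, simulated_run, reference):
        from plasmidqc import parse_sample_sheet, read_fastq

        entries = parse_sample_sheet(
            simulated_run["dir"] / "sample_sheet.csv", {reference.id: reference}
        )
        assert len(entries) == 8
        for e in entries:
            reads = read_fastq(simulated_run["dir"] / f"{e.barcode}.fastq")
            assert reads

    def test_fastq_and_sam_sequences_agree(self, simulated_run):
        """The SAM stores the reference-orientation sequence of the same
        read emitted to FASTQ."""
        from plasmidqc import read_fastq, reverse_complement

        reads = {r.id: r for r in read_fastq(simulated_run["paths"]["barcode01.fastq"])}
        for a in read_alignments(simulated_run["paths"]["barcode01.sam"]):
            if a.mapped and not a.is_supplementary and a.read_sequence:
                fastq_seq = reads[a.read_id].sequence
                expect = (
                    reverse_complement(fastq_seq) if a.strand == "reverse" else fastq_seq
                )
                assert a.read_sequence == expect
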