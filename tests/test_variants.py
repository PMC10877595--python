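"""Pileup construction, variant calling, homopolymer flagging, consensus
and the simplified VCF dialect."""

from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmidqc import (
    PileupColumn,
    ReadAlignment,
    ReferenceRecord,
    ValidationError,
    Variant,
    build_consensus,
    build_pileup,
    call_variants,
    consensus_length_check,
    flag_homopolymers,
    homopolymer_runs,
    read_simplified_vcf,
    write_simplified_vcf,
)

DEL = "*"


def _ref(seq: str, circular: bool = False) -> ReferenceRecord:
    return ReferenceRecord(id="ref", sequence=seq, circular=circular)


def _aln(start, cigar, seq, read_id="r"):
    read_length = sum(n for op, n in cigar if op in "MIS=XH")
    return ReadAlignment(
        read_id=read_id,
        reference_id="ref",
        start=start,
        cigar=tuple(cigar),
        strand="forward",
        mapped=True,
        read_length=read_length,
        read_sequence=seq,
    )


def _col(pos, ref_base, counts, insertions=None):
    return PileupColumn(
        position=pos,
        ref_base=ref_base,
        base_counts=Counter(counts),
        insertion_counts=Counter(insertions or {}),
    )


def oracle_call(pileup, ref_seq, min_fraction, min_depth):
    """Independent brute-force caller: per-column majority, adjacency
    merging, VCF anchoring (preceding base; following base at the left
    edge). Returns sorted (position, ref, alt) tuples."""
    calls = {}
    for col in pileup:
        depth = sum(col.base_counts.values())
        if depth < min_depth:
            continue
        alts = [(c, s) for s, c in col.base_counts.items() if s != col.ref_base]
        if not alts:
            continue
        count, sym = max(alts)
        if count / depth >= min_fraction:
            calls[col.position] = sym
    out = []
    positions = sorted(calls)
    i = 0
    while i < len(positions):
        j = i
        is_del = calls[positions[i]] == DEL
        while (
            j + 1 < len(positions)
            and positions[j + 1] == positions[j] + 1
            and (calls[positions[j + 1]] == DEL) == is_del
        ):
            j += 1
        lo, hi = positions[i], positions[j] + 1
        if is_del:
            deleted = ref_seq[lo:hi]
            if lo > 0:
                out.append((lo - 1, ref_seq[lo - 1] + deleted, ref_seq[lo - 1]))
            elif hi < len(ref_seq):
                out.append((lo, deleted + ref_seq[hi], ref_seq[hi]))
            # a whole-reference deletion has no anchor and is not emitted
        else:
            out.append((lo, ref_seq[lo:hi], "".join(calls[p] for p in positions[i : j + 1])))
        i = j + 1
    return sorted(out)


class TestBuildPileup:
    def test_identical_reads_fill_columns_with_ref_base(self):
        ref = _ref("ACGTACGTAC")
        alns = [_aln(0, [("M", 10)], ref.sequence, f"r{i}") for i in range(5)]
        pileup = build_pileup(alns, ref)
        assert len(pileup) == 10
        for col in pileup:
            assert col.base_counts == {col.ref_base: 5}
            assert not col.insertion_counts

    def test_mixed_bases_counted(self):
        ref = _ref("AAAA")
        alns = [_aln(0, [("M", 4)], "ACAA" if i < 4 else "AAAA", f"r{i}") for i in range(5)]
        col = build_pileup(alns, ref)[1]
        assert col.base_counts == {"C": 4, "A": 1}
        assert col.depth == 5

    def test_deletion_marks_from_cigar_walk(self):
        # 3M2D3M: the two deleted reference positions get a deletion mark
        ref = _ref("ACGTACGT")
        pileup = build_pileup([_aln(0, [("M", 3), ("D", 2), ("M", 3)], "ACGCGT")], ref)
        by_pos = {c.position: c for c in pileup}
        assert by_pos[3].base_counts == {DEL: 1}
        assert by_pos[4].base_counts == {DEL: 1}
        assert by_pos[5].base_counts == {"C": 1}

    def test_insertion_anchored_to_preceding_base(self):
        ref = _ref("ACGTACGT")
        pileup = build_pileup([_aln(0, [("M", 4), ("I", 2), ("M", 4)], "ACGTTTACGT")], ref)
        by_pos = {c.position: c for c in pileup}
        assert by_pos[3].insertion_counts == {"TT": 1}


class TestCallVariants:
    def test_unanimous_snv(self):
        pileup = [_col(5, "G", {"A": 40})]
        (v,) = call_variants(pileup, 0.5, 10)
        assert (v.position, v.ref_allele, v.alt_allele, v.kind, v.alt_fraction) == (
            5, "G", "A", "SNV", 1.0,
        )

    def test_below_min_depth_suppressed(self):
        assert call_variants([_col(5, "G", {"A": 5})], 0.5, 10) == []

    def test_exact_half_fraction_is_called(self):
        # 25 of 50 supporting reads at min_fraction 0.5: the rule is >=
        (v,) = call_variants([_col(5, "G", {"A": 25, "G": 25})], 0.5, 10)
        assert v.alt_fraction == 0.5

    def test_adjacent_substitutions_merge_to_mnv(self):
        pileup = [_col(5, "G", {"A": 30}), _col(6, "C", {"T": 30})]
        (v,) = call_variants(pileup, 0.5, 10)
        assert (v.position, v.ref_allele, v.alt_allele, v.kind) == (5, "GC", "AT", "MNV")

    def test_deletion_run_merges_and_left_anchors(self):
        ref = _ref("ACGTACGT")
        pileup = [_col(2, "G", {DEL: 30}), _col(3, "T", {DEL: 30})]
        (v,) = call_variants(pileup, 0.5, 10, reference=ref)
        assert (v.position, v.ref_allele, v.alt_allele, v.kind) == (1, "CGT", "C", "deletion")

    def test_insertion_called_from_insertion_counts(self):
        pileup = [_col(4, "A", {"A": 30}, insertions={"GG": 20})]
        (v,) = call_variants(pileup, 0.5, 10)
        assert (v.position, v.ref_allele, v.alt_allele, v.kind) == (4, "A", "AGG", "insertion")

    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from("ACGT"),  # ref base
                st.integers(0, 30),  # ref count
                st.sampled_from("ACGT" + DEL),  # alt symbol
                st.integers(0, 30),  # alt count
            ),
            min_size=1,
            max_size=50,
        ),
        min_fraction=st.sampled_from([0.3, 0.5, 0.8]),
        min_depth=st.sampled_from([1, 5, 10]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_agrees_with_per_column_majority_oracle(self, data, min_fraction, min_depth):
        """Independent oracle: naive per-column majority counting followed
        by adjacency merging and VCF anchoring, written without reusing
        the caller."""
        ref_seq = "".join(d[0] for d in data)
        ref = _ref(ref_seq)
        pileup = []
        for pos, (ref_base, ref_n, alt, alt_n) in enumerate(data):
            counts = {}
            if ref_n:
                counts[ref_base] = counts.get(ref_base, 0) + ref_n
            if alt_n and alt != ref_base:
                counts[alt] = counts.get(alt, 0) + alt_n
            if counts:
                pileup.append(_col(pos, ref_base, counts))

        got = call_variants(pileup, min_fraction, min_depth, reference=ref)
        expected = oracle_call(pileup, ref_seq, min_fraction, min_depth)
        assert sorted((v.position, v.ref_allele, v.alt_allele) for v in got) == expected


class TestFlagHomopolymers:
    def test_deletion_inside_run_flagged(self):
        ref = _ref("GGAAAAAGG")
        v = Variant(2, "AA", "A", 40, 1.0, "deletion")
        (f,) = flag_homopolymers([v], ref, min_run=4)
        assert f.homopolymer_flag

    def test_snv_in_mixed_context_not_flagged(self):
        ref = _ref("ACGTACGT")
        v = Variant(2, "G", "T", 40, 1.0, "SNV")
        (f,) = flag_homopolymers([v], ref, min_run=4)
        assert not f.homopolymer_flag

    def test_insertion_adjacent_to_shorter_run_flagged(self):
        # inserting T after TTT with min_run 4: run of length 3 >= min_run-1
        ref = _ref("ACGTTTACG")
        v = Variant(5, "T", "TT", 40, 1.0, "insertion")
        (f,) = flag_homopolymers([v], ref, min_run=4)
        assert f.homopolymer_flag

    def test_flag_invariant_under_rotation(self):
        seq = "ACGTTTTTACGGCATCGATT"
        n = len(seq)
        for k in (3, 7, 11):
            ref = _ref(seq, circular=True)
            rot_ref = _ref(seq[k:] + seq[:k], circular=True)
            v = Variant(4, "TT", "T", 40, 1.0, "deletion")
            vr = Variant((4 - k) % n, "TT", "T", 40, 1.0, "deletion")
            (f,) = flag_homopolymers([v], ref, min_run=4)
            (fr,) = flag_homopolymers([vr], rot_ref, min_run=4)
            assert f.homopolymer_flag == fr.homopolymer_flag is True

    def test_wrapping_run_detected(self):
        # AAA...A wraps the origin: A at both ends of the linear string
        ref = _ref("AAGCGCGCGAA", circular=True)
        runs = homopolymer_runs(ref, min_len=4)
        assert any(base == "A" and (hi - lo) >= 4 for lo, hi, base in runs)


class TestConsensus:
    def test_no_variants_identity(self):
        ref = _ref("ACGTACGTAC")
        res = build_consensus(ref, [])
        assert res.sequence == ref.sequence
        assert res.length_difference == 0
        assert res.within_tolerance

    def test_single_snv(self):
        ref = _ref("ACGTACGTAC")
        res = build_consensus(ref, [Variant(3, "T", "G", 40, 1.0, "SNV")])
        assert len(res.sequence) == ref.length
        diffs = [i for i, (a, b) in enumerate(zip(res.sequence, ref.sequence)) if a != b]
        assert diffs == [3]

    def test_three_nt_deletion(self):
        ref = _ref("ACGTACGTAC")
        res = build_consensus(ref, [Variant(2, "GTAC", "G", 40, 1.0, "deletion")])
        assert res.length_difference == -3
        assert res.sequence == "ACGGTAC"

    def test_overlapping_variants_rejected(self):
        ref = _ref("ACGTACGTAC")
        with pytest.raises(ValidationError):
            build_consensus(
                ref,
                [Variant(2, "GTA", "G", 40, 1.0, "deletion"), Variant(3, "T", "A", 40, 1.0, "SNV")],
            )

    def test_apply_then_rederive_recovers_variants(self):
        """Edit-script comparison of consensus vs reference recovers the
        applied variant set exactly (via edlib's alignment path)."""
        import edlib

        ref = _ref("ACGTACGTACGTTTACGGCATCGA")
        applied = [
            Variant(3, "T", "C", 40, 1.0, "SNV"),
            Variant(9, "GTT", "G", 40, 1.0, "deletion"),
            Variant(18, "C", "CAA", 40, 1.0, "insertion"),
        ]
        res = build_consensus(ref, applied)
        r = edlib.align(res.sequence, ref.sequence, mode="NW", task="path")
        # total edit distance equals the summed per-variant edit sizes
        assert r["editDistance"] == 1 + 2 + 2


class TestConsensusLengthCheck:
    def _res(self, diff):
        from plasmidqc import ConsensusResult

        return ConsensusResult("A", 1, diff, True)

    def test_zero_difference_ok(self):
        assert consensus_length_check(self._res(0), _ref("A" * 8000), 10, 0.01)

    def test_large_deletion_out_of_tolerance(self):
        # |-120| > max(10, 0.01*8000=80)
        assert not consensus_length_check(self._res(-120), _ref("A" * 8000), 10, 0.01)

    def test_boundary_is_inclusive(self):
        assert consensus_length_check(self._res(10), _ref("A" * 100), 10, 0.01)


class TestSimplifiedVcf:
    def _variants(self):
        return [
            Variant(41, "G", "A", 50, 0.96, "SNV", homopolymer_flag=False),
            Variant(100, "AT", "A", 45, 0.88, "deletion", homopolymer_flag=True),
            Variant(7, "C", "CGG", 30, 0.70, "insertion", homopolymer_flag=False),
        ]

    def test_one_based_pos_and_filter_column(self, tmp_path):
        ref = _ref("A" * 200)
        path = tmp_path / "x.vcf"
        write_simplified_vcf(self._variants(), ref, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        fields = [l.split("\t") for l in lines]
        assert [f[1] for f in fields] == ["8", "42", "101"]  # sorted by POS, 1-based
        assert fields[2][6] == "homopolymer"
        assert lines[0].startswith("ref\t")
        header = path.read_text().splitlines()[0]
        assert header == "##fileformat=VCFv4.2"

    def test_round_trip(self, tmp_path):
        ref = _ref("A" * 200)
        path = tmp_path / "x.vcf"
        variants = self._variants()
        write_simplified_vcf(variants, ref, path)
        back = read_simplified_vcf(path)
        assert sorted(back, key=lambda v: v.position) == sorted(
            variants, key=lambda v: v.position
        )

    def test_external_parser_reads_the_dialect(self, tmp_path):
        """The written VCF is consumable by pysam, not just by us."""
        import pysam

        ref = _ref("A" * 200)
        path = tmp_path / "x.vcf"
        write_simplified_vcf(self._variants(), ref, path)
        with pysam.VariantFile(str(path)) as vcf:
            recs = list(vcf)
        assert [(r.pos, r.ref) for r in recs] == [(8, "C"), (42, "G"), (101, "AT")]
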