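"""Shared fixtures: a reference plasmid, a full simulated run, and small
handwritten format fixtures (generated programmatically, text only)."""

from __future__ import annotations

from pathlib import Path

import pytest

from plasmidqc import (
    ReferenceRecord,
    emit_run,
    random_reference,
    run_analysis,
    standard_scenarios,
)

RUN_SEED = 1


@pytest.fixture(scope="session")
def reference() -> ReferenceRecord:
    return random_reference(length=3000, seed=RUN_SEED, circular=True)


@pytest.fixture(scope="session")
def scenarios(reference):
    return standard_scenarios(reference, n_reads=80, seed=RUN_SEED)


@pytest.fixture(scope="session")
def simulated_run(reference, scenarios, tmp_path_factory):
    """One 8-barcode simulated run shared by the whole session."""
    out = tmp_path_factory.mktemp("simrun")
    paths = emit_run(reference, scenarios, out, seed=RUN_SEED)
    return {"dir": out, "paths": paths, "reference": reference, "scenarios": scenarios}


@pytest.fixture(scope="session")
def analyzed_run(simulated_run):
    """The full analysis over the simulated run."""
    d = simulated_run["dir"]
    ref = simulated_run["reference"]
    reports = run_analysis(
        d, d, {ref.id: ref}, d / "sample_sheet.csv", out_dir=d / "analysis"
    )
    return {"reports": reports, "out": d / "analysis", **simulated_run}


@pytest.fixture()
def genbank_file(tmp_path) -> Path:
    """A 120 bp circular GenBank record with an origin-spanning feature
    (location join(101..120,1..20), i.e. 0-based (100,120)+(0,20))."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    seq = ("ACGT" * 30).lower()
    record = SeqRecord(
        Seq(seq),
        id="miniplasmid",
        name="miniplasmid",
        description="synthetic test construct",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    record.features = [
        SeqFeature(
            CompoundLocation([SimpleLocation(100, 120, 1), SimpleLocation(0, 20, 1)]),
            type="misc_feature",
            qualifiers={"label": ["ori_span"]},
        ),
        SeqFeature(
            SimpleLocation(30, 60, 1),
            type="misc_feature",
            qualifiers={"label": ["plain"]},
        ),
    ]
    path = tmp_path / "mini.gb"
    from Bio import SeqIO

    SeqIO.write([record], str(path), "genbank")
    return path


@pytest.fixture()
def sam_file(tmp_path) -> Path:
    """A handwritten SAM exercising FLAG 0/4/16/0x100/0x800 and clips."""
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        "@SQ\tSN:ref1\tLN:100",
        # primary forward, POS 1 -> internal start 0
        "r1\t0\tref1\t1\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t" + "I" * 100,
        # unmapped, length 300
        "r2\t4\t*\t0\t0\t*\t*\t0\t0\t" + "C" * 300 + "\t" + "I" * 300,
        # reverse strand with soft clip
        "r3\t16\tref1\t11\t60\t20S80M\t*\t0\t0\t" + "G" * 100 + "\t" + "I" * 100,
        # secondary: must be dropped
        "r3\t272\tref1\t41\t0\t100M\t*\t0\t0\t*\t*",
        # supplementary for r4
        "r4\t0\tref1\t1\t60\t50M50S\t*\t0\t0\t" + "T" * 100 + "\t" + "I" * 100,
        "r4\t2048\tref1\t61\t60\t50S50M\t*\t0\t0\t" + "T" * 100 + "\t" + "I" * 100,
    ]
    path = tmp_path / "mini.sam"
    path.write_text("\n".join(lines) + "\n")
    return path
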