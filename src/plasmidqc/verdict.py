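"""The four-outcome sample classification.

Evidence from coverage, structural metrics and the variant table is
combined into one of four outcomes, in strict precedence order:

1. ``low_coverage`` — mean depth below the gate (default 30×); the
   sample cannot be judged, typically a sequencing or pooling problem.
2. ``fail`` — any structural problem: a zero-coverage section, a
   majority of reads carrying a large unaligned (insert) segment, a
   consensus length outside tolerance, or more confident
   non-homopolymer variants than the warning envelope allows.
3. ``warning`` — variants exist but all sit within the envelope
   (homopolymer-flagged, i.e. plausibly systematic sequencing error,
   or within the configured non-flagged limit).
4. ``pass`` — nothing to report.

The gate uses mean depth over the whole reference; locally missing
sequence is already policed by the zero-coverage rule. The insert
majority comparison is strict (>): "a majority" means more than half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .alnmetrics import ZeroCoverageSection
from .variants import Variant

OUTCOMES = ("low_coverage", "fail", "warning", "pass")


@dataclass(frozen=True)
class Thresholds:
    """All classification thresholds with their defaults."""

    min_mean_depth: float = 30.0
    min_insert_length: int = 50
    insert_majority_fraction: float = 0.5
    tolerance_abs: int = 10
    tolerance_rel: float = 0.01
    min_fraction: float = 0.5
    min_depth: int = 10
    min_run: int = 4
    warn_nonflagged_variant_limit: int = 0

    def __post_init__(self) -> None:
        positive = (
            self.min_mean_depth,
            self.min_insert_length,
            self.insert_majority_fraction,
            self.min_fraction,
            self.min_depth,
            self.min_run,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("thresholds must be strictly positive")
        if self.warn_nonflagged_variant_limit < 0:
            raise ValueError("warn_nonflagged_variant_limit must be ≥ 0")


@dataclass(frozen=True)
class Reason:
    """A machine-readable reason code with the parameters that triggered it."""

    code: str
    params: tuple[tuple[str, object], ...] = ()

    def to_dict(self) -> dict:
        return {"code": self.code, **dict(self.params)}


@dataclass(frozen=True)
class SampleMetrics:
    """Per-sample evidence, all derived from the same filtered read set."""

    mean_depth: float
    zero_coverage_sections: tuple[ZeroCoverageSection, ...]
    insert_fraction: float
    consensus_within_tolerance: bool
    consensus_length_difference: int
    variants: tuple[Variant, ...]
    n_reads_used: int


@dataclass(frozen=True)
class SampleVerdict:
    outcome: str
    reasons: tuple[Reason, ...]
    metrics: SampleMetrics


def classify_sample(metrics: SampleMetrics, thresholds: Thresholds) -> SampleVerdict:
    """Deterministically map metrics to an outcome with reasons."""
    if metrics.mean_depth < thresholds.min_mean_depth:
        return SampleVerdict(
            outcome="low_coverage",
            reasons=(
                Reason(
                    "low_coverage",
                    (
                        ("mean_depth", metrics.mean_depth),
                        ("min_mean_depth", thresholds.min_mean_depth),
                    ),
                ),
            ),
            metrics=metrics,
        )

    fail_reasons: list[Reason] = []
    for sec in metrics.zero_coverage_sections:
        fail_reasons.append(
            Reason(
                "zero_coverage",
                (("start", sec.start), ("end", sec.end), ("length", sec.length)),
            )
        )
    if metrics.insert_fraction > thresholds.insert_majority_fraction:
        fail_reasons.append(
            Reason("insert_majority", (("fraction", metrics.insert_fraction),))
        )
    if not metrics.consensus_within_tolerance:
        fail_reasons.append(
            Reason(
                "length_out_of_tolerance",
                (("difference", metrics.consensus_length_difference),),
            )
        )
    nonflagged = [v for v in metrics.variants if not v.homopolymer_flag]
    if len(nonflagged) > thresholds.warn_nonflagged_variant_limit:
        fail_reasons.append(
            Reason(
                "variants_over_limit",
                (
                    ("n_nonflagged", len(nonflagged)),
                    ("limit", thresholds.warn_nonflagged_variant_limit),
                ),
            )
        )
    if fail_reasons:
        return SampleVerdict(outcome="fail", reasons=tuple(fail_reasons), metrics=metrics)

    if metrics.variants:
        reasons = tuple(
            Reason(
                "variant",
                (
                    ("position", v.position),
                    ("ref", v.ref_allele),
                    ("alt", v.alt_allele),
                    ("flagged", v.homopolymer_flag),
                ),
            )
            for v in metrics.variants
        )
        return SampleVerdict(outcome="warning", reasons=reasons, metrics=metrics)

    return SampleVerdict(outcome="pass", reasons=(), metrics=metrics)


def classification_boundary(reference, thresholds: Thresholds) -> int:
    """Smallest integer uniform depth not classified low_coverage, scanned
    over 1..2×min_mean_depth. A harness for the coverage gate; accepts a
    ReferenceRecord or a bare length."""
    upper = max(2, int(2 * thresholds.min_mean_depth))
    for depth in range(1, upper + 1):
        metrics = SampleMetrics(
            mean_depth=float(depth),
            zero_coverage_sections=(),
            insert_fraction=0.0,
            consensus_within_tolerance=True,
            consensus_length_difference=0,
            variants=(),
            n_reads_used=depth,
        )
        if classify_sample(metrics, thresholds).outcome != "low_coverage":
            return depth
    return upper
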