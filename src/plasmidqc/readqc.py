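"""Read filtering and run-preview statistics.

Mean read quality is computed in probability space: each Phred score is
converted to an error probability, probabilities are averaged over the
read, and the mean is converted back to a Phred value. This is the
convention of the standard long-read filtering tools, and it weights a
read's worst bases more heavily than an arithmetic mean of Phred scores
would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Read

DEFAULT_MIN_LENGTH = 500
DEFAULT_MIN_MEAN_QUALITY = 8.0
DEFAULT_BIN_WIDTH = 250


def mean_read_quality(read: Read) -> float:
    """Probability-space mean Phred quality of one read."""
    if not read.qualities:
        return 0.0
    probs = np.power(10.0, -np.asarray(read.qualities, dtype=float) / 10.0)
    return float(-10.0 * math.log10(probs.mean()))


def filter_reads(
    reads: Sequence[Read],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
) -> list[Read]:
    """Keep reads of length ≥ min_length and mean quality ≥ min_mean_quality."""
    if min_length < 0 or min_mean_quality < 0:
        raise ValueError("filter thresholds must be non-negative")
    return [
        r
        for r in reads
        if len(r) >= min_length and mean_read_quality(r) >= min_mean_quality
    ]


@dataclass(frozen=True)
class ReadSetStats:
    """Summary statistics of one barcode's read set."""

    n_reads: int
    total_bases: int
    mean_length: float
    median_length: float
    n50: int
    length_histogram: tuple[tuple[int, int, int], ...]

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "total_bases": self.total_bases,
            "mean_length": self.mean_length,
            "median_length": self.median_length,
            "n50": self.n50,
            "length_histogram": [list(b) for b in self.length_histogram],
        }


def _n50(lengths: np.ndarray) -> int:
    """Smallest length L (present in the set) such that reads of length
    ≥ L contain at least half of the total bases."""
    desc = np.sort(lengths)[::-1]
    cum = np.cumsum(desc)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half))
    return int(desc[idx])


def read_set_stats(reads: Sequence[Read], bin_width: int = DEFAULT_BIN_WIDTH) -> ReadSetStats:
    """Compute read-count, length and N50 statistics plus a fixed-width
    length histogram (bins anchored at 0)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not reads:
        return ReadSetStats(0, 0, 0.0, 0.0, 0, ())
    lengths = np.array([len(r) for r in reads], dtype=np.int64)
    n_bins = int(lengths.max() // bin_width) + 1
    counts = np.bincount(lengths // bin_width, minlength=n_bins)
    hist = tuple(
        (i * bin_width, (i + 1) * bin_width, int(c))
        for i, c in enumerate(counts)
        if c > 0 or i < n_bins
    )
    return ReadSetStats(
        n_reads=len(reads),
        total_bases=int(lengths.sum()),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        n50=_n50(lengths),
        length_histogram=hist,
    )
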