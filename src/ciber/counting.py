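"""Assign reads to library barcodes by scaffold-key anchoring.

Each read of a SMART-amplified gRNA spacer contains the 17-nt spacer
immediately followed by the constant 8-nt scaffold prefix ``GTTTAAGA``
(the "key").  A read is assigned to a barcode when the key is found and
the ``spacer_length`` bases directly upstream of it exactly match a
library spacer.  Matching is exact: no mismatches, no indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ciber.errors import ValidationError
from ciber.reference_io import BarcodeReference

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CountingConfig:
    """Parameters of the key-anchored spacer search."""

    key: str = "GTTTAAGA"
    spacer_length: int = 17
    search_window: int | None = None  # max key start position scanned; None = whole read
    try_reverse_complement: bool = False

    def __post_init__(self) -> None:
        problems = []
        if not self.key or not set(self.key) <= set("ACGT"):
            problems.append(f"key {self.key!r} must be a non-empty ACGT string")
        if self.spacer_length < 1:
            problems.append(f"spacer_length must be >= 1, got {self.spacer_length}")
        if self.search_window is not None and self.search_window < 0:
            problems.append(f"search_window must be >= 0, got {self.search_window}")
        if problems:
            raise ValidationError(problems)


@dataclass
class CountingStats:
    """Per-sample counting QC.

    ``coverage`` is the fraction of reference barcodes seen at least once;
    ``skew_ratio`` is the 90th/10th percentile ratio of per-barcode counts
    (infinite when the 10th percentile is zero, flagged by
    ``skew_ratio_defined``).
    """

    total_reads: int = 0
    key_found_reads: int = 0
    assigned_reads: int = 0
    coverage: float = float("nan")
    skew_ratio: float = float("nan")
    skew_ratio_defined: bool = False

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "key_found_reads": self.key_found_reads,
            "assigned_reads": self.assigned_reads,
            "coverage": self.coverage,
            "skew_ratio": None if not np.isfinite(self.skew_ratio) else self.skew_ratio,
            "skew_ratio_defined": self.skew_ratio_defined,
        }


def _find_key(sequence: str, config: CountingConfig) -> int:
    """Position of the first key occurrence with a full spacer upstream, or -1.

    Occurrences starting before ``spacer_length`` cannot carry a full
    spacer; they are skipped and the scan continues downstream.
    """
    limit = len(sequence) if config.search_window is None else min(len(sequence), config.search_window + len(config.key))
    position = sequence.find(config.key, config.spacer_length, limit)
    return position


def assign_read(
    sequence: str,
    spacer_index: Mapping[str, str],
    config: CountingConfig = CountingConfig(),
) -> str | None:
    """Return the barcode_id a read belongs to, or None if unassignable.

    The first key occurrence with room for a full upstream spacer decides:
    if the extracted spacer is not in the library the read stays
    unassigned (no further occurrences are tried for spacer lookup).
    """
    sequence = sequence.upper()
    position = _find_key(sequence, config)
    if position < 0:
        return None
    spacer = sequence[position - config.spacer_length : position]
    return spacer_index.get(spacer)


def count_reads(
    reads: Iterable[tuple[str, str] | str],
    reference: Sequence[BarcodeReference],
    config: CountingConfig = CountingConfig(),
) -> tuple[pd.Series, CountingStats]:
    """Count reads per barcode; returns (counts indexed by barcode_id, stats).

    ``reads`` may yield bare sequences or ``(read_id, sequence)`` pairs.
    Unassignable reads are a counted outcome, not an error.
    """
    if not reference:
        raise ValidationError("reference is empty")
    spacer_index = {r.spacer: r.barcode_id for r in reference}
    if len(spacer_index) != len(reference):
        raise ValidationError("reference spacers are not unique")

    counts: dict[str, int] = {r.barcode_id: 0 for r in reference}
    stats = CountingStats()
    key = config.key
    spacer_length = config.spacer_length

    for read in reads:
        sequence = (read[1] if isinstance(read, tuple) else read).upper()
        stats.total_reads += 1
        position = _find_key(sequence, config)
        if position < 0 and config.try_reverse_complement:
            sequence = reverse_complement(sequence)
            position = _find_key(sequence, config)
        if position < 0:
            continue
        stats.key_found_reads += 1
        barcode = spacer_index.get(sequence[position - spacer_length : position])
        if barcode is not None:
            counts[barcode] += 1
            stats.assigned_reads += 1

    series = pd.Series(counts, name="count", dtype="int64")
    series.index.name = "barcode_id"
    stats.coverage, stats.skew_ratio = coverage_and_skew(series)
    stats.skew_ratio_defined = bool(np.isfinite(stats.skew_ratio))
    return series, stats


def coverage_and_skew(counts: pd.Series | np.ndarray) -> tuple[float, float]:
    """Library QC: (fraction of barcodes with >=1 read, P90/P10 count ratio).

    The skew ratio is reported as ``inf`` when the 10th percentile is zero.
    """
    values = np.asarray(counts, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot compute coverage of an empty count vector")
    coverage = float(np.mean(values > 0))
    p10, p90 = np.percentile(values, [10, 90])
    skew = float(p90 / p10) if p10 > 0 else float("inf")
    return coverage, skew
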