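"""Core genomic interval types and interval algebra.

All coordinates in this package are 0-based half-open ([start, end)),
matching BED/narrowPeak. Conversion to/from other conventions happens only
at parse/serialize boundaries in :mod:`atacqc.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass
class GenomicInterval:
    """A half-open genomic region [start, end) on a contig.

    Backbone of peaks, hotspots, reference peaks and motif sites.
    ``strand`` is "+", "-" or "." (unstranded). ``summit`` is a 0-based
    offset from ``start`` (narrowPeak convention), or None when absent.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AlignedFragment:
    """The sequenced template of a proper read pair, half-open coordinates.

    ``strand`` is the strand of read 1.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    is_proper_pair: bool = True
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment must have positive template length, got "
                f"[{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValueError("fragment start must be >= 0")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModelRecord:
    """A transcript model: tx span plus sorted, non-overlapping exon blocks."""

    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene model strand must be '+' or '-'")
        if self.tx_end <= self.tx_start:
            raise ValueError("tx_end must be > tx_start")
        prev_end = None
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(
                    f"exon block [{s}, {e}) outside tx span "
                    f"[{self.tx_start}, {self.tx_end}) of {self.name!r}"
                )
            if e <= s:
                raise ValueError("exon block must be non-empty")
            if prev_end is not None and s < prev_end:
                raise ValueError("exon blocks must be sorted and non-overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on '+', tx_end - 1 on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


# ---------------------------------------------------------------------------
# Interval algebra on sorted numpy arrays
# ---------------------------------------------------------------------------

def merge_starts_ends(
    starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals given as parallel start/end arrays (any order)."""
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    # running max of ends; a new block starts where start > max(previous ends)
    run_max = np.maximum.accumulate(e)
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > run_max[:-1]
    idx = np.flatnonzero(new_block)
    merged_starts = s[idx]
    merged_ends = np.empty(len(idx), dtype=np.int64)
    merged_ends[:-1] = run_max[idx[1:] - 1]
    merged_ends[-1] = run_max[-1]
    return merged_starts, merged_ends


def by_chrom(
    intervals: Iterable[GenomicInterval], merge: bool = False
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group intervals into per-chrom sorted (starts, ends) arrays."""
    buckets: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        buckets.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in buckets.items():
        arr = np.asarray(pairs, dtype=np.int64)
        starts, ends = arr[:, 0], arr[:, 1]
        if merge:
            starts, ends = merge_starts_ends(starts, ends)
        else:
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
        out[chrom] = (starts, ends)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of a collection of intervals, sorted by (chrom, start)."""
    out: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        starts, ends = by_chrom(
            [iv for iv in intervals if iv.chrom == chrom], merge=True
        )[chrom]
        out.extend(
            GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
        )
    return out


def covered_bases(
    start: int, end: int, merged_starts: np.ndarray, merged_ends: np.ndarray
) -> int:
    """Bases of [start, end) covered by a MERGED sorted interval set."""
    if len(merged_starts) == 0:
        return 0
    lo = int(np.searchsorted(merged_ends, start, side="right"))
    hi = int(np.searchsorted(merged_starts, end, side="left"))
    if hi <= lo:
        return 0
    s = np.maximum(merged_starts[lo:hi], start)
    e = np.minimum(merged_ends[lo:hi], end)
    return int(np.sum(e - s))


def any_overlap(
    start: int, end: int, sorted_starts: np.ndarray, sorted_ends_max: np.ndarray
) -> bool:
    """True if [start, end) overlaps any interval of a merged sorted set."""
    return covered_bases(start, end, sorted_starts, sorted_ends_max) > 0
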