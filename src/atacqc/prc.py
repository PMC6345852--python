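"""Percent Reference peak Coverage (PRC): calibration and scoring.

PRC measures how completely a sample's hotspots cover the open-chromatin
sites that are ubiquitously accessible across many cell types. Calibration
takes a collection of peak sets (e.g. DNase hypersensitivity peaks from
many samples) and keeps the genome bases present in more than a threshold
fraction of them; a sample's PRC is then the percentage of those reference
peaks hit by at least one of its hotspots. Because the reference sites are
open in essentially every cell type, PRC reads out digestion/coverage depth
independently of TSS proximity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GenomicInterval, covered_bases
from .hotspots import HotspotSet


@dataclass
class ReferencePeakSet:
    """Calibrated ubiquitous open-chromatin intervals with provenance."""

    intervals: list[GenomicInterval]
    n_source_sets: int
    presence_threshold: float
    inclusive: bool = False
    species: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.presence_threshold <= 1):
            raise ValueError("presence_threshold must be in (0, 1]")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def calibrate_reference_peaks(
    peak_sets: Sequence[HotspotSet],
    presence_threshold: float = 0.97,
    inclusive: bool = False,
    min_width: int = 20,
    species: str = "",
) -> ReferencePeakSet:
    """Base-level presence calibration across many peak sets.

    A genome base is a candidate when the fraction of sets covering it is
    strictly greater than ``presence_threshold`` (or >= it when
    ``inclusive``, the "common to all samples" mode used with threshold
    1.0). Runs of candidate bases are merged into intervals and slivers
    shorter than ``min_width`` bp are dropped.
    """
    if not peak_sets:
        raise ValueError("at least one peak set required")
    if len(peak_sets) < 2:
        raise ValueError("calibration needs >= 2 peak sets")
    if not (0 < presence_threshold <= 1):
        raise ValueError("presence_threshold must be in (0, 1]")

    n = len(peak_sets)
    # coverage sweep: +1/-1 events from each set's self-merged intervals
    events: dict[str, list[tuple[int, int]]] = {}
    for s in peak_sets:
        for chrom, (starts, ends) in s.merged().items():
            bucket = events.setdefault(chrom, [])
            bucket.extend((int(p), +1) for p in starts)
            bucket.extend((int(p), -1) for p in ends)

    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        evts = np.array(sorted(events[chrom]), dtype=np.int64)
        pos, delta = evts[:, 0], evts[:, 1]
        # collapse coincident positions
        uniq, idx = np.unique(pos, return_index=True)
        depth_step = np.add.reduceat(delta, idx)
        depth = np.cumsum(depth_step)  # coverage on [uniq[i], uniq[i+1])
        frac = depth / n
        passing = frac >= presence_threshold if inclusive else frac > presence_threshold
        start = None
        for i, ok in enumerate(passing):
            seg_start = int(uniq[i])
            seg_end = int(uniq[i + 1]) if i + 1 < len(uniq) else seg_start
            if ok and start is None:
                start = seg_start
            if not ok and start is not None:
                if seg_start - start >= min_width:
                    out.append(GenomicInterval(chrom, start, seg_start))
                start = None
        # depth returns to zero after the last event, so start is closed above
    return ReferencePeakSet(
        out, n_source_sets=n, presence_threshold=presence_threshold,
        inclusive=inclusive, species=species,
    )


def prc(hotspots: HotspotSet, reference: ReferencePeakSet) -> float:
    """Percentage of reference peaks overlapped (>=1 bp) by any hotspot."""
    if len(reference) == 0:
        raise ValueError("reference peak set is empty")
    merged = hotspots.merged()
    hit = 0
    for ref in reference:
        arrs = merged.get(ref.chrom)
        if arrs is not None and covered_bases(ref.start, ref.end, *arrs) > 0:
            hit += 1
    return 100.0 * hit / len(reference)
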