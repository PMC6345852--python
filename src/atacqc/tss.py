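"""TSS enrichment score and TSS-anchored aggregate profiles.

Transposition events are counted in 1-bp bins around every (deduplicated)
transcription start site; minus-strand TSSs are mirrored so positive
offsets always point downstream of transcription. The enrichment score is
the signal-to-noise ratio recommended by ENCODE: mean cut density in a
narrow central window over the mean density in the outermost flanks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GeneModelRecord
from .cutsites import CutSites, normalize_tag_count


@dataclass
class TSSAggregate:
    """Strand-oriented cut counts at offsets -halfwidth .. halfwidth-1."""

    raw_counts: np.ndarray  # int counts summed over TSSs, length 2*halfwidth
    halfwidth: int
    n_tss: int
    total_tags: int
    norm_target: int = 10_000_000

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.halfwidth, self.halfwidth)

    @property
    def counts(self) -> np.ndarray:
        """Counts normalized to ``norm_target`` total library tags."""
        if self.total_tags == 0:
            return self.raw_counts.astype(float)
        return normalize_tag_count(self.raw_counts, self.total_tags, self.norm_target)


def tss_sites(genes: Sequence[GeneModelRecord]) -> list[tuple[str, int, str]]:
    """Deduplicated (chrom, pos, strand) TSS list from a gene model."""
    return sorted({(g.chrom, g.tss, g.strand) for g in genes})


def tss_aggregate(
    cuts: CutSites,
    tss_list: Sequence[tuple[str, int, str]],
    halfwidth: int = 2000,
    norm_target: int = 10_000_000,
) -> TSSAggregate:
    """Accumulate cut counts at 1-bp offsets around each TSS.

    For a minus-strand TSS at p the oriented offset of a cut at genomic
    position g is p - g, so downstream-of-transcription is always positive.
    """
    if not tss_list:
        raise ValueError("tss_list must be non-empty")
    w = halfwidth
    acc = np.zeros(2 * w, dtype=np.int64)
    seen = sorted(set(tss_list))
    for chrom, p, strand in seen:
        pos = cuts.positions(chrom)
        if strand == "-":
            lo, hi = np.searchsorted(pos, (p - w + 1, p + w + 1))
            offs = p - pos[lo:hi]
        else:
            lo, hi = np.searchsorted(pos, (p - w, p + w))
            offs = pos[lo:hi] - p
        if len(offs):
            acc += np.bincount(offs + w, minlength=2 * w)
    return TSSAggregate(
        acc, halfwidth=w, n_tss=len(seen), total_tags=len(cuts),
        norm_target=norm_target,
    )


def tss_score(
    agg: TSSAggregate, center_halfwidth: int = 50, flank_width: int = 100
) -> float:
    """Central mean cut density over outermost-flank mean density.

    Returns +inf (with a warning) when the flanks carry no signal at all;
    uniform signal scores 1.0. The score is invariant to library-size
    normalization because the scaling cancels in the ratio.
    """
    w = agg.halfwidth
    if w < center_halfwidth + flank_width:
        raise ValueError("aggregate window too narrow for score windows")
    counts = agg.raw_counts.astype(float)
    center = counts[w - center_halfwidth : w + center_halfwidth]
    flanks = np.concatenate([counts[:flank_width], counts[-flank_width:]])
    flank_mean = flanks.mean()
    if flank_mean == 0:
        if center.mean() == 0:
            return 0.0
        warnings.warn("flank signal is zero; TSS score reported as +inf")
        return math.inf
    return float(center.mean() / flank_mean)
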