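"""Interval algebra over peak sets: replicate concordance, Venn counts,
genomic-distribution annotation, and peak-anchored tag densities."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    GeneModelRecord,
    GenomicInterval,
    by_chrom,
    covered_bases,
    merge_intervals,
)
from .cutsites import CutSites, normalize_tag_count

CATEGORIES = ("promoter", "exon", "intron", "other", "intergenic")


@dataclass
class HotspotSet:
    """A labelled, sorted collection of peaks ("hotspots")."""

    label: str
    intervals: list[GenomicInterval]
    provenance: str = "pooled"  # pooled | replicate | concordant

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def merged(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return by_chrom(self.intervals, merge=True)


def overlap_fraction(a: GenomicInterval, bs: HotspotSet) -> float:
    """Fraction of a's bases covered by the union of bs on the same chrom."""
    merged = bs.merged().get(a.chrom)
    if merged is None:
        return 0.0
    return covered_bases(a.start, a.end, *merged) / len(a)


def concordant_hotspots(
    pooled: HotspotSet,
    replicates: Sequence[HotspotSet],
    min_frac: float = 0.5,
) -> HotspotSet:
    """Keep pooled peaks covered >= min_frac by EVERY replicate's peak union.

    This is the replicate-concordance filter: peaks called on pooled data
    are retained only when at least half of their bases (by default) are
    supported in each individual replicate. The boundary is inclusive
    ("at least 50%").
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    merged_reps = [rep.merged() for rep in replicates]
    kept = []
    for peak in pooled.intervals:
        ok = True
        for merged in merged_reps:
            arrs = merged.get(peak.chrom)
            frac = (
                covered_bases(peak.start, peak.end, *arrs) / len(peak)
                if arrs is not None
                else 0.0
            )
            if frac < min_frac:
                ok = False
                break
        if ok:
            kept.append(peak)
    return HotspotSet(f"{pooled.label}_concordant", kept, provenance="concordant")


def venn_counts(sets: Sequence[HotspotSet]) -> dict[tuple[str, ...], int]:
    """Venn-region counts for 2 or 3 peak sets.

    Each set is self-merged first; merged intervals from all sets are then
    clustered by >=1 bp overlap, and each cluster contributes one count to
    the region named by the labels present in it. Splitting a peak never
    double-counts because counting is per cluster, not per interval.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts takes 2 or 3 sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be distinct")
    events = []  # (chrom, start, end, label)
    for s in sets:
        for chrom, (starts, ends) in s.merged().items():
            events.extend((chrom, int(a), int(b), s.label) for a, b in zip(starts, ends))
    events.sort(key=lambda t: (t[0], t[1]))
    counts = {
        combo: 0
        for r in range(1, len(labels) + 1)
        for combo in itertools.combinations(sorted(labels), r)
    }
    cluster_members: set[str] = set()
    cur_chrom, cur_end = None, -1
    for chrom, start, end, label in events:
        if chrom != cur_chrom or start >= cur_end:
            if cluster_members:
                counts[tuple(sorted(cluster_members))] += 1
            cluster_members = set()
            cur_chrom, cur_end = chrom, end
        cluster_members.add(label)
        cur_end = max(cur_end, end)
    if cluster_members:
        counts[tuple(sorted(cluster_members))] += 1
    return counts


@dataclass
class GenomicDistribution:
    """Peak counts and fractions over promoter/exon/intron/intergenic/other."""

    counts: dict[str, int]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: self.counts.get(c, 0) / self.total for c in CATEGORIES}


def annotate_distribution(
    peaks: HotspotSet,
    genes: Sequence[GeneModelRecord],
    promoter_up: int = 2000,
    promoter_down: int = 2000,
    tx_end_pad: int = 1000,
) -> GenomicDistribution:
    """Assign each peak one genomic category by its midpoint.

    Precedence: promoter > exon > intron > other > intergenic. The promoter
    is TSS -promoter_up/+promoter_down honoring strand; "other" collects
    midpoints inside a tx span but in neither an exon nor an intron
    (annotation gaps) plus midpoints within tx_end_pad of a transcript end.
    """
    if not genes:
        raise ValueError("gene model must be non-empty")

    promoters, exons, introns, others = [], [], [], []
    for g in genes:
        tss = g.tss
        if g.strand == "+":
            p_start, p_end = tss - promoter_up, tss + promoter_down
            tes = g.tx_end - 1
        else:
            p_start, p_end = tss - promoter_down, tss + promoter_up
            tes = g.tx_start
        promoters.append((g.chrom, max(0, p_start), p_end + 1))
        others.append((g.chrom, max(0, tes - tx_end_pad), tes + tx_end_pad + 1))
        blocks = g.exons or [(g.tx_start, g.tx_end)]
        exons.extend((g.chrom, s, e) for s, e in blocks)
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 > e1:
                introns.append((g.chrom, e1, s2))
        # tx-span gaps outside the first/last exon fall into "other"
        if blocks[0][0] > g.tx_start:
            others.append((g.chrom, g.tx_start, blocks[0][0]))
        if blocks[-1][1] < g.tx_end:
            others.append((g.chrom, blocks[-1][1], g.tx_end))

    def lookup(triples):
        ivs = [GenomicInterval(c, s, e) for c, s, e in triples if e > s]
        return by_chrom(ivs, merge=True) if ivs else {}

    category_maps = {
        "promoter": lookup(promoters),
        "exon": lookup(exons),
        "intron": lookup(introns),
        "other": lookup(others),
    }

    counts = {c: 0 for c in CATEGORIES}
    for peak in peaks:
        mid = peak.midpoint
        for cat in ("promoter", "exon", "intron", "other"):
            arrs = category_maps[cat].get(peak.chrom)
            if arrs is not None and covered_bases(mid, mid + 1, *arrs) > 0:
                counts[cat] += 1
                break
        else:
            counts["intergenic"] += 1
    return GenomicDistribution(counts)


def max_tag_density(
    peaks: HotspotSet, cuts: CutSites, target: int = 10_000_000
) -> np.ndarray:
    """Per-peak maximum per-base cut count, normalized to ``target`` tags."""
    total = len(cuts)
    out = np.zeros(len(peaks.intervals))
    for i, peak in enumerate(peaks):
        pos = cuts.positions(peak.chrom)
        lo, hi = np.searchsorted(pos, (peak.start, peak.end))
        if hi > lo:
            out[i] = np.bincount(pos[lo:hi] - peak.start).max()
    if total == 0:
        return out
    return normalize_tag_count(out, total, target)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation over paired per-peak densities."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 2:
        raise ValueError("correlation requires >= 2 peaks")
    return float(stats.pearsonr(x, y).statistic)


def heatmap_matrix(
    peaks: HotspotSet,
    cuts: CutSites,
    window: int = 5000,
    bin_size: int = 100,
    target: int = 10_000_000,
) -> np.ndarray:
    """Peak-centered cut-count matrix: one row per peak, ±window, binned.

    Entries are cut counts per bin scaled by target / total tags (the
    "reads under the peak / 10 million total reads" convention).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if (2 * window) % bin_size != 0:
        raise ValueError("bin size must divide the 2*window span")
    n_bins = 2 * window // bin_size
    mat = np.zeros((len(peaks.intervals), n_bins))
    for i, peak in enumerate(peaks):
        center = peak.midpoint
        pos = cuts.positions(peak.chrom)
        lo, hi = np.searchsorted(pos, (center - window, center + window))
        if hi > lo:
            bins = (pos[lo:hi] - (center - window)) // bin_size
            mat[i] = np.bincount(bins, minlength=n_bins)
    total = len(cuts)
    if total == 0:
        return mat
    return normalize_tag_count(mat, total, target)


def merged_hotspots(*sets: HotspotSet, label: str = "merged") -> HotspotSet:
    """Union of several hotspot sets as a new merged set."""
    return HotspotSet(
        label,
        merge_intervals([iv for s in sets for iv in s.intervals]),
        provenance="pooled",
    )
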