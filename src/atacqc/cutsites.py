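"""Tn5 cut-site correction and read-level QC quantities.

Tagmentation inserts two adapters per retained fragment, so each proper
pair implies two transposition events. The insertion point sits in the
middle of a 9-bp staggered duplication, which is why the 5' end of a
forward-strand read is shifted +4 bp and the 5' end of a reverse-strand
read (the rightmost aligned base) is shifted -5 bp to land on the centre
of the transposon binding event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .core import AlignedFragment, GenomicInterval
from .io import DEFAULT_MITO_NAMES

TN5_FORWARD_OFFSET = 4
TN5_REVERSE_OFFSET = -5


@dataclass(frozen=True)
class CutSite:
    """A single-base Tn5 transposition event after offset correction."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("cut-site position must be >= 0")


def tn5_shift(fragment: AlignedFragment) -> tuple[CutSite | None, CutSite | None]:
    """Offset-correct both ends of a fragment into cut sites.

    The forward-strand 5' end (fragment start) shifts +4; the reverse-strand
    5' end (rightmost aligned base, ``end - 1``) shifts -5. A shifted
    position that falls below zero is dropped (returned as None).
    """
    fwd_pos = fragment.start + TN5_FORWARD_OFFSET
    rev_pos = (fragment.end - 1) + TN5_REVERSE_OFFSET
    fwd = CutSite(fragment.chrom, fwd_pos, "+") if fwd_pos >= 0 else None
    rev = CutSite(fragment.chrom, rev_pos, "-") if rev_pos >= 0 else None
    return fwd, rev


class CutSites:
    """Column-oriented container of cut sites, sorted per contig.

    Holds per-chrom sorted position arrays with parallel strand arrays
    (True = '+'); every downstream aggregation (TSS profiles, tag
    densities, footprints) works off these arrays.
    """

    def __init__(self, per_chrom: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, fwd) in per_chrom.items():
            pos = np.asarray(pos, dtype=np.int64)
            fwd = np.asarray(fwd, dtype=bool)
            order = np.argsort(pos, kind="stable")
            self.per_chrom[chrom] = (pos[order], fwd[order])

    @classmethod
    def from_fragments(
        cls, fragments: Iterable[AlignedFragment]
    ) -> tuple["CutSites", int]:
        """Shift every fragment; returns (cuts, n_dropped_below_zero)."""
        buckets: dict[str, tuple[list[int], list[bool]]] = {}
        dropped = 0
        for frag in fragments:
            for cut in tn5_shift(frag):
                if cut is None:
                    dropped += 1
                    continue
                pos_list, fwd_list = buckets.setdefault(frag.chrom, ([], []))
                pos_list.append(cut.pos)
                fwd_list.append(cut.strand == "+")
        return cls(
            {c: (np.array(p), np.array(f)) for c, (p, f) in buckets.items()}
        ), dropped

    @classmethod
    def from_sites(cls, sites: Iterable[CutSite]) -> "CutSites":
        buckets: dict[str, tuple[list[int], list[bool]]] = {}
        for s in sites:
            pos_list, fwd_list = buckets.setdefault(s.chrom, ([], []))
            pos_list.append(s.pos)
            fwd_list.append(s.strand == "+")
        return cls({c: (np.array(p), np.array(f)) for c, (p, f) in buckets.items()})

    def __len__(self) -> int:
        return sum(len(pos) for pos, _ in self.per_chrom.values())

    def __iter__(self) -> Iterator[CutSite]:
        for chrom, (pos, fwd) in self.per_chrom.items():
            for p, f in zip(pos, fwd):
                yield CutSite(chrom, int(p), "+" if f else "-")

    def positions(self, chrom: str) -> np.ndarray:
        pos, _ = self.per_chrom.get(chrom, (np.empty(0, np.int64), None))
        return pos

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.positions(chrom)
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    def to_bed(self, path: str) -> None:
        from .io import write_bed

        ivs = [
            GenomicInterval(c.chrom, c.pos, c.pos + 1, strand=c.strand, name="cut")
            for c in self
        ]
        write_bed(path, ivs)

    @classmethod
    def from_bed(cls, path: str) -> "CutSites":
        from .io import read_bed

        return cls.from_sites(
            CutSite(iv.chrom, iv.start, iv.strand if iv.strand != "." else "+")
            for iv in read_bed(path)
        )


def mito_fraction(
    contig_tallies: dict[str, int],
    mito_names: frozenset[str] | set[str] = DEFAULT_MITO_NAMES,
) -> float:
    """Percent of mapped reads on mitochondrial contigs."""
    total = sum(contig_tallies.values())
    if total == 0:
        raise ValueError("no mapped reads tallied")
    mito = sum(n for c, n in contig_tallies.items() if c in mito_names)
    return 100.0 * mito / total


@dataclass
class FragmentSizeProfile:
    """Template-length histogram plus a nucleosome phasing score.

    The phasing score is the spectral power of the mean-subtracted length
    histogram at periods near the mono/di-nucleosome spacing (~190-200 bp),
    as a fraction of total (non-DC) power. Libraries with the laddered
    mono/di/tri-nucleosome size mixture score high; size-homogeneous or
    unstructured libraries score near zero.
    """

    histogram: np.ndarray
    phasing_score: float
    n_fragments: int = 0
    max_length: int = 1000

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(len(self.histogram))


def fragment_size_profile(
    fragments: Iterable[AlignedFragment],
    max_length: int = 1000,
    period_band: tuple[float, float] = (185.0, 215.0),
) -> FragmentSizeProfile:
    hist = np.zeros(max_length + 1, dtype=np.int64)
    n = 0
    for frag in fragments:
        n += 1
        length = len(frag)
        if length <= max_length:
            hist[length] += 1
    if hist.sum() == 0:
        return FragmentSizeProfile(hist, 0.0, n_fragments=n, max_length=max_length)
    centered = hist - hist.mean()
    power = np.abs(np.fft.rfft(centered)) ** 2
    power[0] = 0.0
    total = power.sum()
    if total == 0:
        return FragmentSizeProfile(hist, 0.0, n_fragments=n, max_length=max_length)
    size = len(centered)
    with np.errstate(divide="ignore"):
        periods = size / np.arange(len(power), dtype=float)
    band = (periods >= period_band[0]) & (periods <= period_band[1])
    score = float(power[band].sum() / total)
    return FragmentSizeProfile(hist, score, n_fragments=n, max_length=max_length)


def normalize_tag_count(
    counts: np.ndarray, total_tags: int, target: int = 10_000_000
) -> np.ndarray:
    """Scale per-position counts so the library totals ``target`` tags.

    The 10-million target is the histogram/heatmap convention; footprint
    profiles use 100 million.
    """
    if total_tags <= 0:
        raise ValueError("total_tags must be > 0")
    return np.asarray(counts, dtype=float) * (target / total_tags)
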