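"""Digital genomic footprinting with hexamer cut-bias correction.

A transcription factor bound at its motif shields the DNA from Tn5, so cut
counts dip over the motif relative to the surrounding open chromatin. The
footprint statistic aggregates observed cut counts over all genome-wide
motif matches inside open chromatin, compares them with counts expected
from Tn5's intrinsic hexamer sequence preference (estimated genome-wide
from the same library), and summarises the dip as the mean flank-adjusted
log2(observed/expected) over the motif positions.

The module also provides the inputs to that statistic: log-odds PWM
construction, exact p-value score thresholds by dynamic programming over
the discretized score distribution, a both-strand motif scanner, and a
brute-force k-mer mappability mask used to exclude ambiguous positions
from both observed and expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import GenomicInterval
from .cutsites import CutSites
from .hotspots import HotspotSet
from .io import Genome, PositionFrequencyMatrix

UNIFORM_BG = np.full(4, 0.25)
N_HEXAMERS = 4096
_POW4_DESC = 4 ** np.arange(5, -1, -1)  # most-significant base first
_POW4_ASC = 4 ** np.arange(6)


# ---------------------------------------------------------------------------
# PWMs, exact p-value thresholds, scanning
# ---------------------------------------------------------------------------

@dataclass
class PWMModel:
    """Log-odds position weight matrix with its background model."""

    scores: np.ndarray  # (4, W) log2 odds
    background: np.ndarray
    motif_id: str = ""
    granularity: float = 1e-3  # score discretization (bits) for the p-value DP

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background probabilities must sum to 1")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("every PWM score must be finite")

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    def max_score(self) -> float:
        return float(self.scores.max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.scores.min(axis=0).sum())


def build_pwm(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> PWMModel:
    """Standard log-odds construction from base counts.

    score[b, j] = log2( (count[b,j] + pc*bg[b]) / (coltotal[j] + pc) / bg[b] ).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background must have strictly positive entries")
    counts = pfm.counts
    col_tot = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (col_tot + pseudocount)
    return PWMModel(np.log2(probs / bg[:, None]), bg, motif_id=pfm.motif_id)


def score_distribution(pwm: PWMModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact score distribution of a random background word, discretized.

    Column scores are rounded to ``pwm.granularity`` bits and convolved
    column-by-column under the background base probabilities. Returns
    (scores, probabilities) with scores ascending; probabilities sum to 1.
    """
    g = pwm.granularity
    ints = np.rint(pwm.scores / g).astype(np.int64)  # (4, W)
    # DP over columns on the integer score lattice
    dist = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.width):
        col = ints[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(dist) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = cur_lo + int(col[b]) - new_lo
            new[shift : shift + len(dist)] += pwm.background[b] * dist
        dist, cur_lo = new, new_lo
    support = np.flatnonzero(dist > 0)
    return (cur_lo + support) * g, dist[support]


def score_threshold(pwm: PWMModel, p: float = 1e-4) -> float:
    """Smallest achievable score t with P(random word score >= t) <= p.

    When even the single best word exceeds probability ``p`` the maximum
    achievable score is returned. Exact at the DP granularity.
    """
    if p <= 0 or p > 1:
        raise ValueError("p must be in (0, 1]")
    scores, probs = score_distribution(pwm)
    tail = np.cumsum(probs[::-1])[::-1]  # P(score >= scores[i])
    ok = np.flatnonzero(tail <= p)
    if len(ok) == 0:
        return float(scores[-1])
    return float(scores[ok[0]])


@dataclass
class MotifSite:
    """A PWM match: forward-strand half-open coordinates plus match strand."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("motif site must have positive width")

    @property
    def width(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.end, strand=self.strand, score=self.score
        )


def scan_motifs(
    genome: Genome, pwm: PWMModel, threshold: float
) -> list[MotifSite]:
    """Scan both strands of every contig for windows scoring >= threshold.

    Windows containing non-ACGT bases are skipped. Reverse-strand matches
    are reported on forward-strand coordinates with strand '-'.
    """
    w = pwm.width
    # 5th row (-inf) poisons any window containing an ambiguous base
    aug = np.vstack([pwm.scores, np.full(w, -np.inf)])
    rc = aug[[3, 2, 1, 0, 4], ::-1]  # revcomp PWM scanned on the forward strand
    sites: list[MotifSite] = []
    for chrom, seq in genome.sequences.items():
        codes = genome.codes(chrom)
        n = len(codes) - w + 1
        if n <= 0:
            continue
        for strand, mat in (("+", aug), ("-", rc)):
            acc = np.zeros(n)
            for j in range(w):
                acc += mat[codes[j : j + n], j]
            hits = np.flatnonzero(acc >= threshold)
            sites.extend(
                MotifSite(chrom, int(h), int(h) + w, strand, float(acc[h]))
                for h in hits
            )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def intersect_open(
    sites: Sequence[MotifSite], peaks: HotspotSet
) -> list[MotifSite]:
    """Keep motif sites overlapping >= 1 bp of any open-chromatin peak."""
    from .core import covered_bases

    merged = peaks.merged()
    out = []
    for s in sites:
        arrs = merged.get(s.chrom)
        if arrs is not None and covered_bases(s.start, s.end, *arrs) > 0:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Mappability
# ---------------------------------------------------------------------------

@dataclass
class MappabilityMask:
    """Per-position flags: the k-mer starting here maps uniquely.

    Uniqueness counts genomic loci over both strands: a k-mer maps uniquely
    when it and its reverse complement together occur at exactly one locus.
    A position is usable for a forward-strand cut at p via the k-mer
    starting at p, and for a reverse-strand cut via the k-mer ending at p
    (the read extends 3' from the cut on its own strand).
    """

    unique: dict[str, np.ndarray]
    k: int

    def unique_at(self, chrom: str, pos: int, strand: str) -> bool:
        arr = self.unique.get(chrom)
        if arr is None:
            return False
        idx = pos if strand == "+" else pos - self.k + 1
        if idx < 0 or idx >= len(arr):
            return False
        return bool(arr[idx])

    def strand_arrays(self, chrom: str, length: int) -> tuple[np.ndarray, np.ndarray]:
        """(plus_ok, minus_ok) boolean arrays over positions 0..length-1."""
        arr = self.unique.get(chrom)
        plus = np.zeros(length, dtype=bool)
        minus = np.zeros(length, dtype=bool)
        if arr is not None:
            plus[: len(arr)] = arr
            minus[self.k - 1 : self.k - 1 + len(arr)] = arr
        return plus, minus


def mappability_mask(genome: Genome, k: int = 50) -> MappabilityMask:
    """Brute-force k-mer uniqueness catalog over both strands.

    Intended for desk-scale genomes; for real genomes supply a precomputed
    mask through :class:`MappabilityMask` directly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    chrom_windows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    fwd_rows, rc_rows = [], []
    for chrom in genome.sequences:
        codes = genome.codes(chrom)
        if k > len(codes):
            raise ValueError(f"k={k} exceeds length of contig {chrom!r}")
        win = sliding_window_view(codes, k)
        valid = (win < 4).all(axis=1)
        rcwin = (3 - win[:, ::-1].astype(np.int8)).astype(np.uint8)
        chrom_windows[chrom] = (win, rcwin, valid)
        fwd_rows.append(win[valid])
        rc_rows.append(rcwin[valid])
    stacked = np.concatenate(fwd_rows + rc_rows, axis=0)
    if len(stacked) == 0:
        return MappabilityMask(
            {c: np.zeros(len(w[0]), bool) for c, w in chrom_windows.items()}, k
        )
    _, inverse, counts = np.unique(
        stacked, axis=0, return_inverse=True, return_counts=True
    )
    n_fwd = sum(len(r) for r in fwd_rows)
    per_pos_counts = counts[inverse[:n_fwd]]
    unique: dict[str, np.ndarray] = {}
    offset = 0
    for chrom, (win, rcwin, valid) in chrom_windows.items():
        m = int(valid.sum())
        t = per_pos_counts[offset : offset + m]
        palindrome = (win[valid] == rcwin[valid]).all(axis=1)
        # a palindrome contributes 2 catalog rows per locus
        uniq_valid = np.where(palindrome, t == 2, t == 1)
        arr = np.zeros(len(win), dtype=bool)
        arr[valid] = uniq_valid
        unique[chrom] = arr
        offset += m
    return MappabilityMask(unique, k)


# ---------------------------------------------------------------------------
# Hexamer bias model
# ---------------------------------------------------------------------------

class HexamerCodes:
    """Per-position hexamer codes for both strands of a genome.

    The hexamer frame is the window [p-3, p+3) around the cut base p;
    minus-strand cuts read the reverse complement of the same window.
    Positions where the window leaves the contig or contains an ambiguous
    base carry code -1.
    """

    def __init__(self, genome: Genome):
        self.plus: dict[str, np.ndarray] = {}
        self.minus: dict[str, np.ndarray] = {}
        for chrom in genome.sequences:
            codes = genome.codes(chrom).astype(np.int64)
            length = len(codes)
            plus = np.full(length, -1, dtype=np.int64)
            minus = np.full(length, -1, dtype=np.int64)
            if length >= 6:
                win = sliding_window_view(codes, 6)  # window start j -> p = j + 3
                valid = (win < 4).all(axis=1)
                fwd = win @ _POW4_DESC
                rc = (3 - win) @ _POW4_ASC
                p = np.arange(3, 3 + len(win))
                plus[p[valid]] = fwd[valid]
                minus[p[valid]] = rc[valid]
            self.plus[chrom] = plus
            self.minus[chrom] = minus


def hexamer_string(code: int) -> str:
    return "".join("ACGT"[(code >> (2 * (5 - i))) & 3] for i in range(6))


@dataclass
class HexamerBiasModel:
    """Relative Tn5 cut rate per hexamer, with genomic abundances.

    ``rates`` are observed cut fractions per hexamer (sum 1 over observed
    hexamers); ``abundance`` the fraction of usable genome position-strand
    slots carrying each hexamer. The expected relative cut intensity at a
    position is rate(hexamer) / abundance(hexamer): the abundance
    normalization converts cut frequencies into per-slot preferences.
    """

    rates: np.ndarray  # (4096,)
    abundance: np.ndarray  # (4096,)
    total_cuts: int
    frame: str = "[-3,+3) around the cut base, revcomp on minus strand"
    _weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.rates < 0) or np.any(self.abundance < 0):
            raise ValueError("rates and abundances must be non-negative")

    def expected_weight(self) -> np.ndarray:
        """Per-hexamer relative cut preference rate/abundance (0 if unseen)."""
        if self._weights is None:
            w = np.zeros(N_HEXAMERS)
            ok = self.abundance > 0
            w[ok] = self.rates[ok] / self.abundance[ok]
            self._weights = w
        return self._weights


def _genomic_abundance(
    hexcodes: HexamerCodes, mask: MappabilityMask, lengths: dict[str, int]
) -> np.ndarray:
    tally = np.zeros(N_HEXAMERS, dtype=np.int64)
    for chrom, length in lengths.items():
        plus_ok, minus_ok = mask.strand_arrays(chrom, length)
        hp, hm = hexcodes.plus[chrom], hexcodes.minus[chrom]
        sel_p = plus_ok & (hp >= 0)
        sel_m = minus_ok & (hm >= 0)
        tally += np.bincount(hp[sel_p], minlength=N_HEXAMERS)
        tally += np.bincount(hm[sel_m], minlength=N_HEXAMERS)
    total = tally.sum()
    if total == 0:
        raise ValueError("no usable (unique, unambiguous) genome positions")
    return tally / total


def hexamer_model(
    cuts: CutSites,
    genome: Genome,
    mask: MappabilityMask,
    hexcodes: HexamerCodes | None = None,
) -> HexamerBiasModel:
    """Estimate the per-hexamer cut-rate model from a cut-site library.

    Each cut tallies the hexamer covering [p-3, p+3) (reverse complement
    for minus-strand cuts); cuts at non-unique or ambiguous positions are
    excluded, as are the corresponding genome slots from the abundance.
    """
    hexcodes = hexcodes or HexamerCodes(genome)
    lengths = genome.lengths()
    tally = np.zeros(N_HEXAMERS, dtype=np.int64)
    for chrom, (pos, fwd) in cuts.per_chrom.items():
        if chrom not in lengths:
            continue
        length = lengths[chrom]
        plus_ok, minus_ok = mask.strand_arrays(chrom, length)
        hp, hm = hexcodes.plus[chrom], hexcodes.minus[chrom]
        inb = pos < length
        p_plus = pos[fwd & inb]
        p_minus = pos[~fwd & inb]
        p_plus = p_plus[plus_ok[p_plus] & (hp[p_plus] >= 0)]
        p_minus = p_minus[minus_ok[p_minus] & (hm[p_minus] >= 0)]
        tally += np.bincount(hp[p_plus], minlength=N_HEXAMERS)
        tally += np.bincount(hm[p_minus], minlength=N_HEXAMERS)
    total = int(tally.sum())
    if total == 0:
        raise ValueError("no cuts remain after mappability/ambiguity masking")
    return HexamerBiasModel(
        rates=tally / total,
        abundance=_genomic_abundance(hexcodes, mask, lengths),
        total_cuts=total,
    )


def planted_bias_model(
    bias_weights: np.ndarray,
    genome: Genome,
    mask: MappabilityMask,
    hexcodes: HexamerCodes | None = None,
) -> HexamerBiasModel:
    """Bias model implied by known per-hexamer preferences.

    Builds the model whose expected weights equal ``bias_weights`` exactly
    on this genome, for studies where the generating preferences are known.
    """
    hexcodes = hexcodes or HexamerCodes(genome)
    abundance = _genomic_abundance(hexcodes, mask, genome.lengths())
    rates = np.asarray(bias_weights, dtype=float) * abundance
    total = rates.sum()
    if total <= 0:
        raise ValueError("planted bias assigns zero rate to every present hexamer")
    return HexamerBiasModel(rates=rates / total, abundance=abundance, total_cuts=0)


# ---------------------------------------------------------------------------
# Footprint profiles
# ---------------------------------------------------------------------------

@dataclass
class FootprintProfile:
    """Observed/expected cut profile around aggregated motif sites.

    Offsets run -flank .. width-1+flank relative to the motif start
    (strand-oriented). ``depth`` is the mean baseline-adjusted log2 ratio
    over the motif offsets; the baseline is the mean log2 ratio over the
    outermost flank offsets, so a bias-only library scores ~0.
    """

    offsets: np.ndarray
    observed: np.ndarray  # normalized to norm_target tags
    expected: np.ndarray  # same normalization, total matched to observed
    log2_ratio: np.ndarray
    adjusted_log2_ratio: np.ndarray
    baseline: float
    depth: float
    motif_width: int
    flank: int
    n_sites: int
    norm_target: int

    def to_tsv(self, path: str) -> None:
        header = "offset\tobserved\texpected\tlog2ratio\tadjusted_log2ratio\n"
        with open(path, "w") as fh:
            fh.write(header)
            for o, ob, ex, lr, alr in zip(
                self.offsets, self.observed, self.expected,
                self.log2_ratio, self.adjusted_log2_ratio,
            ):
                fh.write(f"{o}\t{ob:.6g}\t{ex:.6g}\t{lr:.6g}\t{alr:.6g}\n")


def footprint_profile(
    cuts: CutSites,
    sites: Sequence[MotifSite],
    bias: HexamerBiasModel,
    mask: MappabilityMask,
    genome: Genome,
    flank: int = 25,
    total_tags: int | None = None,
    norm_target: int = 100_000_000,
    epsilon: float = 0.5,
    baseline_frac: float = 0.4,
    hexcodes: HexamerCodes | None = None,
) -> FootprintProfile:
    """Aggregate observed and bias-expected cut counts around motif sites.

    Per offset, observed counts sum strand-oriented cuts over all sites
    (mappability-masked positions excluded per cut strand) and are scaled
    to ``norm_target`` library tags; expected counts sum the per-position
    hexamer preferences under the same masking and are scaled so their
    window total matches the observed total. The per-offset deviation is
    log2((obs+eps)/(exp+eps)); the flank baseline (mean deviation over the
    outermost ``baseline_frac`` of each flank) is subtracted and the depth
    is the mean adjusted deviation over the motif offsets.
    """
    if not sites:
        raise ValueError("no motif sites supplied")
    widths = {s.width for s in sites}
    if len(widths) != 1:
        raise ValueError("all motif sites must share one width")
    w = widths.pop()
    span = w + 2 * flank
    hexcodes = hexcodes or HexamerCodes(genome)
    weights = bias.expected_weight()
    lengths = genome.lengths()

    obs = np.zeros(span)
    exp = np.zeros(span)
    strand_masks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for site in sites:
        chrom = site.chrom
        if chrom not in lengths:
            continue
        length = lengths[chrom]
        if chrom not in strand_masks:
            strand_masks[chrom] = mask.strand_arrays(chrom, length)
        plus_ok, minus_ok = strand_masks[chrom]
        hp, hm = hexcodes.plus[chrom], hexcodes.minus[chrom]
        pos, fwd = cuts.per_chrom.get(chrom, (np.empty(0, np.int64), np.empty(0, bool)))

        if site.strand == "-":
            q = (site.end - 1 + flank) - np.arange(span)
        else:
            q = (site.start - flank) + np.arange(span)
        inb = (q >= 0) & (q < length)
        qi = q[inb]
        ok_p = plus_ok[qi] & (hp[qi] >= 0)
        ok_m = minus_ok[qi] & (hm[qi] >= 0)
        # observed: per-base cut counts at the window positions
        win_lo, win_hi = qi.min(), qi.max() + 1
        lo, hi = np.searchsorted(pos, (win_lo, win_hi))
        local = np.zeros(win_hi - win_lo, dtype=np.int64)
        local_m = np.zeros(win_hi - win_lo, dtype=np.int64)
        if hi > lo:
            seg, segf = pos[lo:hi] - win_lo, fwd[lo:hi]
            np.add.at(local, seg[segf], 1)
            np.add.at(local_m, seg[~segf], 1)
        o = np.zeros(span)
        e = np.zeros(span)
        o[inb] = local[qi - win_lo] * ok_p + local_m[qi - win_lo] * ok_m
        e[inb] = np.where(ok_p, weights[hp[qi]], 0.0) + np.where(
            ok_m, weights[hm[qi]], 0.0
        )
        obs += o
        exp += e

    if exp.sum() == 0:
        raise ValueError("expected profile is identically zero")
    total = total_tags if total_tags is not None else len(cuts)
    if total <= 0:
        raise ValueError("total_tags must be > 0")
    scale = norm_target / total
    obs_n = obs * scale
    exp_n = exp * (obs.sum() / exp.sum()) * scale

    log2_ratio = np.log2((obs_n + epsilon) / (exp_n + epsilon))
    n_base = max(1, int(round(baseline_frac * flank)))
    baseline_idx = np.r_[0:n_base, span - n_base : span]
    baseline = float(log2_ratio[baseline_idx].mean())
    adjusted = log2_ratio - baseline
    depth = float(adjusted[flank : flank + w].mean())
    return FootprintProfile(
        offsets=np.arange(-flank, w + flank),
        observed=obs_n,
        expected=exp_n,
        log2_ratio=log2_ratio,
        adjusted_log2_ratio=adjusted,
        baseline=baseline,
        depth=depth,
        motif_width=w,
        flank=flank,
        n_sites=len(sites),
        norm_target=norm_target,
    )
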