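"""Synthetic ATAC-seq data with known ground truth.

Emulates the features of a real library that the QC and footprinting
metrics respond to: TSS-enriched cut sites over a background, hexamer-
dependent Tn5 insertion bias, planted TF footprints (local cut depletion
over motifs), nucleosomal fragment-size periodicity, mitochondrial
contamination, and replicate peak collections with controlled presence
fractions. Everything is deterministic per seed, and every generator
returns a truth record sufficient to compute the expected value of each
metric without re-reading generator internals.

The cut model: per-position, per-strand cut intensity on the main contig is

    base * hexamer_weight(hexamer at p, strand)
         * (1 + (A - 1) * sum_tss exp(-(p - tss)^2 / (2 sigma^2)))
         * protection_factor (over planted motif positions)
         * open-region indicator

Fragments pair a forward cut with a reverse cut re-sampled from the same
intensity in a +/-pair_window around (forward cut + a nucleosome-mixture
length), so both ends follow the planted intensity while fragment lengths
follow the mono/di/tri-nucleosome mixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core import AlignedFragment, GeneModelRecord, GenomicInterval
from .cutsites import CutSites
from .footprint import HexamerCodes, MotifSite, N_HEXAMERS
from .hotspots import HotspotSet
from .io import Genome, reverse_complement

_MIN_FRAG_LEN = 36  # keeps both cuts ordered even at the pairing-window edge
_MAX_FRAG_LEN = 1000


@dataclass
class FragmentLengthMixture:
    """Mono/di/tri-nucleosome Gaussian mixture of template lengths (bp)."""

    weights: tuple[float, ...] = (0.50, 0.35, 0.15)
    means: tuple[float, ...] = (75.0, 265.0, 455.0)
    sds: tuple[float, ...] = (15.0, 25.0, 30.0)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        lengths = rng.normal(
            np.asarray(self.means)[comp], np.asarray(self.sds)[comp]
        )
        return np.clip(np.rint(lengths), _MIN_FRAG_LEN, _MAX_FRAG_LEN).astype(
            np.int64
        )


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic library."""

    seed: int = 0
    genome_length: int = 200_000
    mito_length: int = 16_000
    main_contig: str = "chr1"
    mito_contig: str = "chrM"
    alphabet: str = "ACGT"
    n_genes: int = 20
    n_fragments: int = 200_000
    tss_enrichment_factor: float = 5.0
    tss_sigma: float = 75.0
    mito_fraction: float = 0.05
    hexamer_bias: np.ndarray | None = None  # (4096,) weights; None = uniform
    motif_consensus: str | None = None
    n_motif_sites: int = 0
    protection_factor: float = 1.0
    open_regions: list[tuple[int, int]] | None = None
    mixture: FragmentLengthMixture = field(default_factory=FragmentLengthMixture)
    pair_window: int = 20

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("main contig must be >= 10 kb")
        if not (0 <= self.mito_fraction <= 1):
            raise ValueError("mito_fraction must be in [0, 1]")
        if self.protection_factor < 0:
            raise ValueError("protection factor must be >= 0")
        if self.motif_consensus and len(self.motif_consensus) > self.genome_length:
            raise ValueError("motif longer than genome")

    def truth_params(self) -> dict:
        d = asdict(self)
        d["hexamer_bias"] = (
            None if self.hexamer_bias is None else list(map(float, self.hexamer_bias))
        )
        return d


def make_genome(
    spec: SimulationSpec,
) -> tuple[Genome, list[GeneModelRecord], dict]:
    """Random genome with planted motif instances and a known gene model.

    The mitochondrial contig carries no genes and no planted motifs so the
    contamination metric stays orthogonal to the others. Deterministic per
    seed (the generator stream is independent of the cut simulator's).
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(spec.alphabet))
    main = rng.choice(letters, size=spec.genome_length)
    mito = rng.choice(letters, size=spec.mito_length)

    motif_sites: list[MotifSite] = []
    if spec.motif_consensus and spec.n_motif_sites > 0:
        w = len(spec.motif_consensus)
        margin = 2000
        usable = spec.genome_length - 2 * margin
        slot = usable // spec.n_motif_sites
        if slot < w + 200:
            raise ValueError("too many motif sites for this genome length")
        for i in range(spec.n_motif_sites):
            start = margin + i * slot + int(rng.integers(0, slot - w - 100))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = (
                spec.motif_consensus
                if strand == "+"
                else reverse_complement(spec.motif_consensus)
            )
            main[start : start + w] = list(seq)
            motif_sites.append(MotifSite(spec.main_contig, start, start + w, strand, 0.0))

    genes: list[GeneModelRecord] = []
    if spec.n_genes > 0:
        margin = 6000
        usable = spec.genome_length - 2 * margin
        slot = usable // spec.n_genes
        if slot < 3000:
            raise ValueError("too many genes for this genome length")
        for i in range(spec.n_genes):
            anchor = margin + i * slot + int(rng.integers(0, max(1, slot - 3000)))
            tx_len = int(rng.integers(2000, 3000))
            strand = "+" if i % 2 == 0 else "-"
            tx_start, tx_end = anchor, anchor + tx_len
            # three exons with two introns
            e1 = (tx_start, tx_start + 200)
            e2 = (tx_start + tx_len // 2, tx_start + tx_len // 2 + 150)
            e3 = (tx_end - 200, tx_end)
            genes.append(
                GeneModelRecord(
                    spec.main_contig, strand, tx_start, tx_end,
                    exons=[e1, e2, e3], name=f"gene{i}",
                )
            )

    genome = Genome(
        {spec.main_contig: "".join(main), spec.mito_contig: "".join(mito)}
    )
    truth = {
        "seed": spec.seed,
        "params": spec.truth_params(),
        "motif_sites": [
            {"chrom": s.chrom, "start": s.start, "end": s.end, "strand": s.strand}
            for s in motif_sites
        ],
        "tss": [
            {"chrom": g.chrom, "pos": g.tss, "strand": g.strand} for g in genes
        ],
    }
    return genome, genes, truth


def cut_intensity(
    spec: SimulationSpec,
    genome: Genome,
    genes: Sequence[GeneModelRecord],
    motif_sites: Sequence[MotifSite] = (),
    hexcodes: HexamerCodes | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(plus, minus) per-position cut intensities on the main contig."""
    length = len(genome[spec.main_contig])
    if spec.hexamer_bias is not None:
        hexcodes = hexcodes or HexamerCodes(genome)
        bias = np.append(np.asarray(spec.hexamer_bias, dtype=float), 0.0)
        hp = hexcodes.plus[spec.main_contig]
        hm = hexcodes.minus[spec.main_contig]
        plus = bias[np.where(hp >= 0, hp, N_HEXAMERS)]
        minus = bias[np.where(hm >= 0, hm, N_HEXAMERS)]
    else:
        plus = np.ones(length)
        minus = np.ones(length)

    pos = np.arange(length, dtype=float)
    kernel = np.ones(length)
    amp = spec.tss_enrichment_factor - 1.0
    if amp != 0:
        for g in genes:
            kernel += amp * np.exp(
                -((pos - g.tss) ** 2) / (2 * spec.tss_sigma**2)
            )
    plus = plus * kernel
    minus = minus * kernel

    if spec.protection_factor != 1.0:
        for s in motif_sites:
            plus[s.start : s.end] *= spec.protection_factor
            minus[s.start : s.end] *= spec.protection_factor

    if spec.open_regions is not None:
        keep = np.zeros(length, dtype=bool)
        for a, b in spec.open_regions:
            keep[a:b] = True
        plus = np.where(keep, plus, 0.0)
        minus = np.where(keep, minus, 0.0)

    # guard the contig edges so shifted fragment ends stay on-contig
    plus[:10] = 0.0
    plus[-10:] = 0.0
    minus[:10] = 0.0
    minus[-10:] = 0.0
    return plus, minus


def _sample_positions(
    intensity: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    total = intensity.sum()
    if total <= 0:
        raise ValueError("cut intensity is identically zero")
    counts = rng.multinomial(n, intensity / total)
    return np.repeat(np.arange(len(intensity)), counts)


def draw_cuts(
    spec: SimulationSpec,
    genome: Genome,
    genes: Sequence[GeneModelRecord],
    motif_sites: Sequence[MotifSite] = (),
    n_cuts: int | None = None,
    rng: np.random.Generator | None = None,
) -> CutSites:
    """Draw cut sites i.i.d. from the planted intensity (no pairing).

    Used for studies that analyse transposition events directly; strand is
    an independent fair coin per cut weighted by the strand intensities.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    n = n_cuts if n_cuts is not None else 2 * spec.n_fragments
    plus, minus = cut_intensity(spec, genome, genes, motif_sites)
    both = np.concatenate([plus, minus])
    flat = _sample_positions(both, n, rng)
    length = len(plus)
    fwd = flat < length
    pos = np.where(fwd, flat, flat - length)
    order = np.argsort(pos, kind="stable")
    return CutSites({spec.main_contig: (pos[order], fwd[order])})


def simulate_fragments(
    spec: SimulationSpec,
    genome: Genome,
    genes: Sequence[GeneModelRecord],
    motif_sites: Sequence[MotifSite] = (),
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignedFragment], CutSites, dict]:
    """Fragment population with nucleosomal lengths and mito contamination.

    Returns (fragments incl. mitochondrial, non-mito cut sites, truth).
    The emitted cut sites are exactly what Tn5 offset correction recovers
    from the fragments on the main contig.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    n_mito = int(rng.binomial(spec.n_fragments, spec.mito_fraction))
    n_main = spec.n_fragments - n_mito
    plus, minus = cut_intensity(spec, genome, genes, motif_sites)
    length = len(plus)

    c1 = _sample_positions(plus, n_main, rng)
    rng.shuffle(c1)
    lengths = spec.mixture.sample(n_main, rng)
    targets = np.clip(c1 + lengths, 0, length - 11)
    c2 = _pair_reverse_cuts(targets, minus, spec.pair_window, rng)
    c2 = np.maximum(c2, c1 + 15)

    fragments: list[AlignedFragment] = []
    read1_minus = rng.random(n_main) < 0.5
    for a, b, m in zip(c1, c2, read1_minus):
        fragments.append(
            AlignedFragment(
                spec.main_contig, int(a) - 4, int(b) + 6,
                strand="-" if m else "+",
            )
        )

    if n_mito > 0:
        mito_len = len(genome[spec.mito_contig])
        m_lengths = spec.mixture.sample(n_mito, rng)
        m_lengths = np.minimum(m_lengths, mito_len - 20)
        m_starts = rng.integers(4, mito_len - m_lengths - 10)
        for s, ln in zip(m_starts, m_lengths):
            fragments.append(AlignedFragment(spec.mito_contig, int(s), int(s + ln)))

    pos = np.concatenate([c1, c2])
    fwd = np.concatenate([np.ones(n_main, bool), np.zeros(n_main, bool)])
    cuts = CutSites({spec.main_contig: (pos, fwd)})
    truth = {
        "seed": spec.seed,
        "n_fragments": spec.n_fragments,
        "n_mito": n_mito,
        "params": spec.truth_params(),
    }
    return fragments, cuts, truth


def _pair_reverse_cuts(
    targets: np.ndarray,
    minus_intensity: np.ndarray,
    window: int,
    rng: np.random.Generator,
    block: int = 100_000,
) -> np.ndarray:
    """Sample reverse-cut positions near targets, weighted by intensity."""
    offsets = np.arange(-window, window + 1)
    length = len(minus_intensity)
    out = np.empty(len(targets), dtype=np.int64)
    for lo in range(0, len(targets), block):
        t = targets[lo : lo + block]
        cand = np.clip(t[:, None] + offsets[None, :], 0, length - 1)
        w = minus_intensity[cand]
        row_sum = w.sum(axis=1, keepdims=True)
        # a fully closed window falls back to the nominal target position
        fallback = row_sum[:, 0] <= 0
        w[fallback] = 0.0
        w[fallback, window] = 1.0
        row_sum[fallback, 0] = 1.0
        cdf = np.cumsum(w, axis=1) / row_sum
        u = rng.random(len(t))[:, None]
        idx = (u > cdf).sum(axis=1)
        out[lo : lo + block] = cand[np.arange(len(t)), idx]
    return out


# ---------------------------------------------------------------------------
# Peak-set collections for reference-peak calibration
# ---------------------------------------------------------------------------

def simulate_peak_collections(
    n_sets: int,
    planted_presence_fractions: Sequence[float],
    n_loci_per_fraction: int = 10,
    peak_width: int = 200,
    jitter: int = 20,
    n_private: int = 40,
    chrom: str = "chr1",
    coordinate_span: int = 1_000_000,
    seed: int = 0,
) -> tuple[list[HotspotSet], dict]:
    """Replicate peak sets with ubiquitous loci at controlled presence.

    Each planted locus is inserted (with +/-jitter coordinate noise) into
    ``round(fraction * n_sets)`` of the sets; private peaks fill the second
    half of the coordinate span so they never contaminate planted loci.
    """
    if n_sets < 2:
        raise ValueError("need at least 2 peak sets")
    for f in planted_presence_fractions:
        if not (0 <= f <= 1):
            raise ValueError("presence fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    half = coordinate_span // 2
    loci = []
    spacing = peak_width + 4 * jitter + 100
    n_loci = len(planted_presence_fractions) * n_loci_per_fraction
    if n_loci * spacing > half:
        raise ValueError("too many planted loci for the coordinate span")
    i = 0
    for frac in planted_presence_fractions:
        n_present = int(round(frac * n_sets))
        for _ in range(n_loci_per_fraction):
            start = 1000 + i * spacing
            loci.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + peak_width,
                    "presence_fraction": n_present / n_sets,
                    "n_present": n_present,
                }
            )
            i += 1

    sets: list[HotspotSet] = []
    membership = [
        rng.choice(n_sets, size=locus["n_present"], replace=False)
        for locus in loci
    ]
    for s in range(n_sets):
        ivs = []
        for locus, members in zip(loci, membership):
            if s in members:
                shift = int(rng.integers(-jitter, jitter + 1))
                ivs.append(
                    GenomicInterval(
                        chrom, locus["start"] + shift, locus["end"] + shift
                    )
                )
        starts = rng.integers(half, coordinate_span - peak_width, size=n_private)
        ivs.extend(GenomicInterval(chrom, int(a), int(a) + peak_width) for a in starts)
        sets.append(HotspotSet(f"set{s}", ivs, provenance="replicate"))
    truth = {"seed": seed, "n_sets": n_sets, "loci": loci}
    return sets, truth


def write_truth(path: str, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
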