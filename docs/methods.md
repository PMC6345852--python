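# Methods

This note documents the models behind each metric, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Coordinates and cut-site correction

All coordinates are 0-based half-open, matching BED/narrowPeak;
conversions happen only at parse/serialize boundaries. Tn5 inserts as a
dimer that duplicates 9 bp, so the centre of a transposition event sits
+4 bp from a forward read's 5′ end and −5 bp from a reverse read's 5′ end
(the rightmost aligned base). Both ends of each proper pair are emitted as
cut sites; the two cuts of a fragment coincide at template length 10 and
are strictly ordered from length 11 up. A shifted position below zero is
dropped and tallied. Equivalent reverse-offset formulations circulate in
the field; this one is frozen and unit-tested. Duplicate fragments are
kept by default (coordinate dedup is opt-in), the MAPQ filter defaults to
0, secondary/supplementary alignments are skipped by default, and
mitochondrial contigs default to {chrM, chrMT, MT, M} — all configurable.

## Fragment-size phasing score

The template-length histogram (1-bp bins, capped at 1,000 bp to mirror
typical library size selection) is mean-subtracted and Fourier-analysed;
the phasing score is the spectral power at periods of 185–215 bp — the
mono/di-nucleosome spacing — as a fraction of total non-DC power. It
quantifies the nucleosome ladder that is otherwise judged by eye from an
electropherogram: laddered libraries score high, size-homogeneous or
unstructured ones near zero. The score is a relative diagnostic; only
comparisons between libraries are meaningful.

## Replicate concordance and Venn counting

A pooled peak is retained when, for every replicate, at least 50%
(inclusive) of the pooled peak's bases are covered by the union of that
replicate's peaks. The denominator is the pooled peak because the pooled
peak is the retained object; the threshold fraction is a parameter. The
filter is monotone: raising the threshold never adds peaks. Venn counts
self-merge each set, cluster intervals across sets by ≥1-bp overlap, and
count one per cluster per membership region, so a peak split in one set
cannot be double-counted.

## Genomic distribution

Each peak is assigned one category by its midpoint with precedence
promoter > exon > intron > other > intergenic. The promoter is TSS
±2,000 bp (strand-honoured; symmetric with the TSS-score window), "other"
collects midpoints inside a transcript span that fall in neither an exon
nor an intron, plus midpoints within 1 kb of a transcript end. These
windows are conventions, not biology; they are parameters with the stated
defaults.

## TSS enrichment score

Transposition events — offset-corrected cut sites, not whole reads — are
counted in 1-bp bins at strand-oriented offsets within ±2,000 bp of each
deduplicated TSS and normalized to 10 M library tags. The score divides
the mean per-bp count in the central ±50 bp by the mean in the two
outermost 100-bp flanks. Uniform libraries score 1.0; the score is
invariant to library-size scaling. Zero flank signal with central signal
returns +inf with a warning. The central/flank construction is the
standard ENCODE-style one; other published variants (e.g. different flank
widths, max-vs-mean centres) change the absolute value, so scores should
only be compared within one convention.

## Reference-peak calibration and PRC

Calibration is base-level: for a collection of n peak sets, a genome base
is a candidate when the fraction of sets covering it is strictly greater
than the presence threshold (default 0.97); an inclusive ≥ mode supports
"common to all samples" calibration at threshold 1.0. Candidate bases
merge into intervals and slivers under 20 bp are dropped. Base-level
counting (rather than clustering whole peaks first) is robust to peak
fragmentation across sources; the 20-bp minimum suppresses jitter
slivers. PRC is 100 × (reference peaks overlapped ≥1 bp by any hotspot) /
(reference peaks): the denominator is the reference, which is what makes
the metric a coverage-depth readout — a few thousand ubiquitous reference
peaks against tens of thousands of sample hotspots.

## PWM scanning and exact p-value thresholds

PWMs are log2-odds with a pseudocount (default 0.8, background-weighted).
The p-value→score threshold is computed exactly by dynamic programming:
column scores are rounded to a 10⁻³-bit lattice and convolved under the
background base distribution; the threshold is the smallest achievable
score whose tail probability is ≤ p, falling back to the maximum
achievable score when even the best word is more probable than p. The
lattice granularity trades table size against exactness and is validated
against exhaustive word enumeration for widths 3–8. Scanning covers both
strands (reverse strand via the reverse-complemented matrix on forward
coordinates) and skips windows containing non-ACGT bases.

## Mappability

Position i is unique when the k-mer starting there occurs at exactly one
genomic locus counting both strands (a single-locus palindrome is
unique). k defaults to 50, matching a typical in-silico read trim length.
The catalog is brute force by design — the tool targets desk-scale and
synthetic genomes — and `MappabilityMask` accepts precomputed per-contig
boolean arrays for real genomes. A forward-strand cut at p is usable via
the k-mer starting at p; a reverse-strand cut via the k-mer ending at p
(the read extends 3′ from the cut on its own strand).

## Hexamer bias model and footprint depth

Tn5 prefers some insertion sequences. The model tallies, for each cut,
the hexamer covering [p−3, p+3) around the cut base (reverse-complemented
for minus-strand cuts; the frame is recorded in the model), excluding
non-unique positions. Rates are cut fractions per hexamer; genome-wide
hexamer abundances over the same unique position-strand slots convert
them to per-slot preferences, expected weight = rate / abundance. The
abundance normalization is required: without it a bias-only library would
show spurious structure wherever local hexamer composition deviates from
the genome average.

Footprint profiles aggregate, per strand-oriented offset across all motif
sites (motif ± 25 bp flank by default), observed cut counts and expected
per-position weights, both mappability-masked, both normalized to 100 M
tags, with the expected total matched to the observed total inside the
window (the coupling between the two normalizations is otherwise
undefined). The per-offset deviation is log2((obs+ε)/(exp+ε)) with
ε = 0.5 guarding empty bins. The baseline — the mean deviation over the
outermost 40% of each flank — is subtracted, and the depth is the mean
adjusted deviation over the motif offsets, so a bias-only library scores
≈ 0 and a motif protected by factor f scores ≈ log2 f.

## Synthetic data generator

The generator is first-class, tested code. Per-position, per-strand cut
intensity on the main contig is the product of a hexamer preference, a
Gaussian TSS enrichment kernel (amplitude = enrichment factor at the TSS,
σ = 75 bp), a protection factor over planted motif bases and an optional
open-region indicator. The Gaussian kernel and the ±20 bp peak-coordinate
jitter in the peak-collection generator were chosen so analytic
expectations (the central/flank kernel ratio for the TSS score; presence
fractions for calibration) are computable in closed form; both are spec
fields, not constants. Fragments draw a forward cut from the intensity, a
template length from a mono/di/tri-nucleosome Gaussian mixture (weights
0.50/0.35/0.15, means 75/265/455 bp, sd 15/25/30 bp), and re-sample the
reverse cut from the intensity inside a ±20 bp window around the nominal
end, so both fragment ends follow the planted intensity while lengths
follow the mixture; `draw_cuts` samples cut sites i.i.d. from the
intensity for studies that analyse transposition events directly. A
binomial share of fragments lands uniformly on the mitochondrial contig,
which carries no genes or motifs so the contamination metric stays
orthogonal. Default study sizes: 200-kb main contig, 16-kb mito contig,
20 genes, 200k fragments, 5× enrichment, 5% mito.

What the generator does not emulate: real sequence composition (i.i.d.
bases, so mappability is trivially high at k = 50), read-level errors and
alignment artefacts, copy-number or chromatin-domain structure, overlap
between peak presence classes, and motif matches arising by chance inside
planted open regions. Passing tests therefore demonstrate that the
estimators recover planted parameters under the stated noise model — not
that real libraries meet any particular threshold.

Validation study sizes were chosen so that sampling noise sits well below
each tolerance: hexamer-rate recovery uses a two-letter complement-closed
(A/T) 100-kb sequence, which keeps reverse-complement hexamers inside the
same 64-class set (≈15k cuts per hexamer at 10⁶ cuts, ≈1% relative SE);
footprint null/depth studies confine the open regions to the site windows
so each profile offset aggregates ≈16k cuts.

## Known limitations

- The mappability catalog and motif scan are O(genome) in memory and not
  meant for mammalian-scale genomes inside this package; supply
  precomputed masks and site lists there.
- Absolute TSS-score values are convention-dependent (see above).
- The concordance filter and PRC treat peaks as given; no re-calling or
  differential analysis is attempted.
- PRC with very small calibrated references is quantized (each reference
  peak is worth 100/n percentage points).
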