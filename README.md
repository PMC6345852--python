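# atacqc

Quality control and digital footprinting for ATAC-seq libraries.

ATAC-seq maps open chromatin by letting the hyperactive Tn5 transposase
insert sequencing adapters into accessible DNA. Judging whether a library
is good — sufficiently digested, low in mitochondrial contamination,
reproducible across replicates — requires more than read counts. `atacqc`
implements the computational QC layer that sits between an aligner and a
biological analysis, for anyone benchmarking ATAC protocols, storage
conditions, or input cell numbers:

- **Tn5 cut-site correction.** Each retained fragment implies two
  transposition events. The 5′ end of a forward-strand read is shifted
  +4 bp and the reverse-strand 5′ end (the rightmost aligned base) −5 bp,
  so every cut site marks the centre of the 9-bp transposon binding event.
- **TSS enrichment score.** Transposition events are counted in 1-bp bins
  within ±2,000 bp of every RefSeq-style TSS (strand-oriented, normalized
  to 10 M tags); the score is the mean cut density in the central ±50 bp
  over the mean density in the outermost 100-bp flanks — a signal-to-noise
  ratio that is 1.0 for featureless libraries.
- **PRC (Percent Reference peak Coverage).** Reference peaks are genome
  bases open in more than a threshold fraction (default >97%) of a large
  collection of peak sets — chromatin that essentially every cell type
  keeps accessible. PRC = 100 × (reference peaks overlapped ≥1 bp by the
  sample's hotspots) / (reference peaks): a digestion-depth readout that,
  unlike the TSS score, is not anchored to promoters.
- **Replicate-concordant hotspots.** Peaks called on pooled replicates are
  retained only when ≥50% of their bases are covered by each individual
  replicate's peaks; plus Venn region counts, per-peak maximum tag
  densities with Pearson correlation, TSS histograms, peak-centred heatmap
  matrices, and promoter/exon/intron/intergenic/other annotation.
- **Digital footprinting.** Motif sites found by log-odds PWM scanning at
  an exact p < 10⁻⁴ threshold (dynamic programming over the discretized
  score distribution) and restricted to open chromatin are aggregated into
  observed cut profiles (normalized to 100 M tags). Expected profiles come
  from a hexamer cut-preference model — the frequency of each 6-mer
  centred on the cut base, abundance-normalized and mappability-masked.
  The footprint depth is the mean flank-baseline-adjusted
  log2(observed/expected) over the motif: ~0 for unbound motifs,
  log2(protection) for bound ones.
- **Synthetic data.** A fully seeded generator plants every signal above
  (TSS enrichment, hexamer bias, footprints, nucleosomal fragment-length
  periodicity, mitochondrial contamination, controlled peak-set presence)
  with machine-readable ground truth, so every metric is testable end to
  end without external data.

## Worked example

`examples/footprint_depth.py` plants 150 copies of an 11-bp motif whose
bases are protected 4-fold from Tn5 in a genome with lognormal hexamer
bias, then recovers the footprint:

```
sites aggregated:  150
flank baseline:    +0.221 log2 units
footprint depth:   -2.004  (planted log2(0.25) = -2.000)
```

The depth equals log2 of the planted protection factor: the hexamer
expected model absorbs the sequence bias (which alone shifts the raw log
ratio by the +0.22 baseline), and the motif offsets drop ~2 log2 units
below the flanks. `examples/qc_report.py` runs the full QC quartet on a
simulated 100k-fragment library with 5× TSS enrichment and 5%
mitochondrial contamination:

```
hotspots (concordant): 20
PRC:                   50.0%
TSS score:             3.55
mitochondrial reads:   5.01%
```

and `examples/reference_calibration.py` shows the presence-threshold
calibration separating loci present in 98.4% vs 95.2% of 125 peak sets.

## Command line

```sh
atacqc simulate --seed 11 --n-fragments 20000 --outdir demo/
atacqc cuts --bam demo/fragments.bed --out demo/cuts.bed
atacqc prc-calibrate --peaks-dir demo/peaksets --threshold 0.97 --out demo/reference.bed
atacqc qc --bam demo/fragments.bed \
    --pooled demo/peaksets/set0.narrowPeak \
    --rep demo/peaksets/set1.narrowPeak --rep demo/peaksets/set2.narrowPeak \
    --reference demo/reference.bed --genes demo/genes.bed12 \
    --json demo/report.json
```

`atacqc tss`, `atacqc footprint`, `atacqc hotspots` and `atacqc annotate`
expose the remaining metrics; every command reads plain SAM/BAM, BED,
narrowPeak, BED12/refFlat, FASTA or JASPAR text and writes BED/TSV/JSON.

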