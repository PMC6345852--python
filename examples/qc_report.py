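"""Full QC quartet on a synthetic library.

Simulates a paired-end ATAC library with 5x TSS enrichment and 5%
mitochondrial contamination, then computes the four headline QC numbers:
concordant hotspot count, PRC, TSS enrichment score and % mitochondrial
reads.
"""

import numpy as np

from atacqc import (
    CutSites,
    GenomicInterval,
    HotspotSet,
    ReferencePeakSet,
    SimulationSpec,
    concordant_hotspots,
    make_genome,
    mito_fraction,
    prc,
    simulate_fragments,
    tss_aggregate,
    tss_score,
    tss_sites,
)

spec = SimulationSpec(seed=1, n_fragments=100_000,
                      tss_enrichment_factor=5.0, mito_fraction=0.05)
genome, genes, _ = make_genome(spec)
fragments, _, _ = simulate_fragments(spec, genome, genes)

tallies: dict[str, int] = {}
for f in fragments:
    tallies[f.chrom] = tallies.get(f.chrom, 0) + 1
mito = mito_fraction(tallies)

nuclear = [f for f in fragments if f.chrom != "chrM"]
cuts, _ = CutSites.from_fragments(nuclear)
score = tss_score(tss_aggregate(cuts, tss_sites(genes)))

pooled = HotspotSet("pooled", [
    GenomicInterval("chr1", g.tss - 1000, g.tss + 1000) for g in genes
])
reps = [
    HotspotSet(f"rep{i}", [GenomicInterval(p.chrom, p.start + d, p.end + d)
                           for p in pooled])
    for i, d in enumerate((25, -25))
]
hotspots = concordant_hotspots(pooled, reps)

# toy reference: half the peaks sit at TSSs this sample covers, half elsewhere
reference = ReferencePeakSet(
    [GenomicInterval("chr1", g.tss - 50, g.tss + 50) for g in genes[:10]]
    + [GenomicInterval("chrM", 1000 + i * 200, 1100 + i * 200) for i in range(10)],
    n_source_sets=125, presence_threshold=0.97,
)
coverage = prc(hotspots, reference)

print(f"hotspots (concordant): {len(hotspots)}")
print(f"PRC:                   {coverage:.1f}%")
print(f"TSS score:             {score:.2f}")
print(f"mitochondrial reads:   {mito:.2f}%")
print()
print("The sample keeps every pooled peak (replicates nearly coincide),")
print("covers exactly the reachable half of the reference peaks, shows the")
print("planted ~3.5x TSS signal-to-noise, and ~5% mitochondrial reads.")
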