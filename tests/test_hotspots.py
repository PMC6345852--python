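import numpy as np
import pytest

from atacqc import (
    CutSites,
    GeneModelRecord,
    GenomicInterval,
    HotspotSet,
    annotate_distribution,
    concordant_hotspots,
    heatmap_matrix,
    max_tag_density,
    overlap_fraction,
    pearson_r,
    venn_counts,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def hs(label, *pairs, chrom="chr1"):
    return HotspotSet(label, [iv(s, e, chrom) for s, e in pairs])


class TestOverlapFraction:
    def test_single_overlap(self):
        assert overlap_fraction(iv(0, 100), hs("b", (0, 60))) == 0.6

    def test_union_not_double_counted(self):
        assert overlap_fraction(iv(0, 100), hs("b", (20, 40), (30, 70))) == 0.5

    def test_empty_set(self):
        assert overlap_fraction(iv(0, 100), HotspotSet("b", [])) == 0.0

    def test_agrees_with_per_base_oracle(self, rng, per_base_oracle):
        for _ in range(300):
            a_start = int(rng.integers(0, 400))
            a = iv(a_start, a_start + int(rng.integers(1, 120)))
            n = int(rng.integers(0, 8))
            members = []
            for _ in range(n):
                s = int(rng.integers(0, 500))
                members.append(iv(s, s + int(rng.integers(1, 80))))
            got = overlap_fraction(a, HotspotSet("b", members))
            want = per_base_oracle(a.start, a.end, members) / len(a)
            assert got == pytest.approx(want, abs=1e-12)


class TestConcordance:
    def test_rejected_when_any_replicate_below_half(self):
        pooled = hs("pooled", (0, 100))
        rep1, rep2 = hs("r1", (0, 60)), hs("r2", (0, 40))
        assert len(concordant_hotspots(pooled, [rep1, rep2])) == 0

    def test_exact_half_retained(self):
        pooled = hs("pooled", (0, 100))
        reps = [hs("r1", (0, 50)), hs("r2", (50, 100))]
        assert len(concordant_hotspots(pooled, reps)) == 1

    def test_identity_retains_all(self):
        pooled = hs("pooled", (0, 100), (200, 350), (400, 401))
        out = concordant_hotspots(pooled, [pooled, pooled])
        assert [(p.start, p.end) for p in out] == [(0, 100), (200, 350), (400, 401)]

    def test_output_subset_and_monotone(self, rng, random_hotspots_factory):
        pooled = random_hotspots_factory(rng, 60, label="pooled")
        reps = [random_hotspots_factory(rng, 60, label=f"r{i}") for i in range(2)]
        pooled_keys = {(p.chrom, p.start, p.end) for p in pooled}
        prev = None
        for frac in (0.1, 0.3, 0.5, 0.8, 1.0):
            out = {(p.chrom, p.start, p.end)
                   for p in concordant_hotspots(pooled, reps, frac)}
            assert out <= pooled_keys
            if prev is not None:
                assert out <= prev  # raising min_frac never adds peaks
            prev = out

    def test_bad_min_frac_rejected(self):
        with pytest.raises(ValueError):
            concordant_hotspots(hs("p", (0, 10)), [hs("r", (0, 10))], min_frac=0.0)


class TestVenn:
    def test_overlapping_pair_is_one_shared_cluster(self):
        counts = venn_counts([hs("A", (0, 10)), hs("B", (5, 15))])
        assert counts[("A", "B")] == 1
        assert counts[("A",)] == 0 and counts[("B",)] == 0

    def test_disjoint_chromosomes(self):
        counts = venn_counts([hs("A", (0, 10)), hs("B", (0, 10), chrom="chr2")])
        assert counts[("A",)] == 1 and counts[("B",)] == 1 and counts[("A", "B")] == 0

    def test_identical_sets_share_everything(self):
        a = hs("A", (0, 10), (100, 150))
        b = hs("B", (0, 10), (100, 150))
        counts = venn_counts([a, b])
        assert counts == {("A",): 0, ("B",): 0, ("A", "B"): 2}

    def test_three_sets_and_order_invariance(self):
        a, b, c = hs("A", (0, 10)), hs("B", (5, 15)), hs("C", (100, 110))
        c1 = venn_counts([a, b, c])
        c2 = venn_counts([c, a, b])
        assert c1 == c2
        assert c1[("A", "B")] == 1 and c1[("C",)] == 1

    def test_more_than_three_sets_rejected(self):
        with pytest.raises(ValueError):
            venn_counts([hs(l, (0, 10)) for l in "ABCD"])


class TestAnnotate:
    GENES = [
        GeneModelRecord("chr1", "+", 10_000, 16_000,
                        exons=[(10_000, 10_500), (12_000, 12_300), (15_500, 16_000)],
                        name="g+"),
    ]

    def categorize(self, mid):
        peaks = HotspotSet("p", [iv(mid - 50, mid + 50)])
        dist = annotate_distribution(peaks, self.GENES)
        return next(c for c, n in dist.counts.items() if n == 1)

    def test_upstream_midpoint_is_promoter(self):
        assert self.categorize(9_500) == "promoter"

    def test_promoter_beats_exon(self):
        # midpoint within 2 kb of the TSS and inside exon 1
        assert self.categorize(10_400) == "promoter"

    def test_exon_midpoint(self):
        assert self.categorize(12_150) == "exon"

    def test_intron_midpoint(self):
        assert self.categorize(13_500) == "intron"

    def test_tx_end_pad_is_other(self):
        assert self.categorize(16_500) == "other"

    def test_intergenic_far_away(self):
        assert self.categorize(80_000) == "intergenic"

    def test_geneless_contig_is_intergenic(self):
        peaks = HotspotSet("p", [iv(100, 200, chrom="chr9")])
        dist = annotate_distribution(peaks, self.GENES)
        assert dist.counts["intergenic"] == 1

    def test_fractions_sum_to_one(self, rng, random_hotspots_factory):
        peaks = random_hotspots_factory(rng, 200, label="p")
        dist = annotate_distribution(peaks, self.GENES)
        assert sum(dist.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(dist.counts.values()) == len(peaks)

    def test_empty_gene_model_rejected(self):
        with pytest.raises(ValueError):
            annotate_distribution(hs("p", (0, 10)), [])


class TestTagDensity:
    def _cuts(self, positions):
        return CutSites({"chr1": (np.array(positions), np.ones(len(positions), bool))})

    def test_identical_replicates_correlate_perfectly(self, rng):
        peaks = hs("p", (0, 100), (200, 300), (400, 500))
        cuts = self._cuts(sorted(rng.integers(0, 500, size=200)))
        d1 = max_tag_density(peaks, cuts)
        assert pearson_r(d1, d1) == pytest.approx(1.0)

    def test_scaling_invariance(self):
        assert pearson_r([1, 2, 4], [10, 20, 40]) == pytest.approx(1.0)

    def test_anti_ordered(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0], [2.0])

    def test_max_density_is_max_per_base_count(self):
        peaks = hs("p", (0, 100))
        cuts = self._cuts([10, 10, 10, 50])
        dens = max_tag_density(peaks, cuts, target=4)  # target == total: identity
        assert dens[0] == 3.0


class TestHeatmap:
    def test_point_mass_in_central_bin(self):
        peaks = hs("p", (990, 1010))  # center 1000
        cuts = CutSites({"chr1": (np.array([1000]), np.array([True]))})
        mat = heatmap_matrix(peaks, cuts, window=500, bin_size=100)
        assert mat.shape == (1, 10)
        assert mat[0, 5] == pytest.approx(1e7 / 1)
        assert mat.sum() == pytest.approx(1e7)

    def test_uniform_cuts_roughly_flat(self, rng):
        peaks = hs("p", (4990, 5010))
        pos = np.sort(rng.integers(0, 10_000, size=100_000))
        cuts = CutSites({"chr1": (pos, np.ones(len(pos), bool))})
        mat = heatmap_matrix(peaks, cuts, window=5000, bin_size=1000)
        assert mat.std() / mat.mean() < 0.05

    def test_zero_cuts_all_zero(self):
        mat = heatmap_matrix(hs("p", (0, 100)), CutSites({}), window=500, bin_size=100)
        assert not mat.any()

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError):
            heatmap_matrix(hs("p", (0, 100)), CutSites({}), window=500, bin_size=300)
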