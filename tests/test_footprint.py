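import itertools

import numpy as np
import pytest

from atacqc import (
    CutSites,
    Genome,
    GenomicInterval,
    HotspotSet,
    MappabilityMask,
    MotifSite,
    PositionFrequencyMatrix,
    build_pwm,
    footprint_profile,
    hexamer_model,
    intersect_open,
    mappability_mask,
    planted_bias_model,
    scan_motifs,
    score_distribution,
    score_threshold,
)
from atacqc.simulate import SimulationSpec, draw_cuts, make_genome


class TestBuildPwm:
    def test_uniform_column_scores_zero(self):
        pfm = PositionFrequencyMatrix(np.full((4, 4), 5.0))
        pwm = build_pwm(pfm)
        np.testing.assert_allclose(pwm.scores, 0.0, atol=1e-12)

    def test_small_pseudocount_approaches_log2_of_four(self):
        counts = np.zeros((4, 4))
        counts[0] = 100.0  # all-A columns
        counts[1:, :] += 1e-9
        pwm = build_pwm(PositionFrequencyMatrix(counts + 1e-12), pseudocount=1e-9)
        assert pwm.scores[0, 0] == pytest.approx(2.0, abs=1e-4)

    def test_negative_pseudocount_rejected(self):
        pfm = PositionFrequencyMatrix(np.full((4, 4), 5.0))
        with pytest.raises(ValueError):
            build_pwm(pfm, pseudocount=-1)

    def test_zero_background_rejected(self):
        pfm = PositionFrequencyMatrix(np.full((4, 4), 5.0))
        with pytest.raises(ValueError):
            build_pwm(pfm, background=np.array([0.5, 0.5, 0.0, 0.0]))


def enumerate_tail(pwm):
    """Brute-force word enumeration at the DP granularity."""
    g = pwm.granularity
    ints = np.rint(pwm.scores / g).astype(np.int64)
    scores, probs = {}, {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(ints[b, j] for j, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        probs[s] = probs.get(s, 0.0) + p
    support = np.array(sorted(probs))
    return support * g, np.array([probs[s] for s in support])


class TestScoreThreshold:
    @pytest.mark.parametrize("background", [None, np.array([0.4, 0.1, 0.1, 0.4])])
    def test_dp_equals_enumeration_width4(self, rng, background):
        pfm = PositionFrequencyMatrix(rng.integers(1, 30, size=(4, 4)).astype(float))
        pwm = build_pwm(pfm, background=background)
        s_dp, p_dp = score_distribution(pwm)
        s_en, p_en = enumerate_tail(pwm)
        np.testing.assert_allclose(s_dp, s_en, atol=1e-9)
        np.testing.assert_allclose(p_dp, p_en, atol=1e-12)

    def test_p_one_gives_minimum_achievable_score(self, toy_pfm):
        pwm = build_pwm(toy_pfm)
        s, _ = score_distribution(pwm)
        assert score_threshold(pwm, 1.0) == pytest.approx(s[0])

    def test_tiny_p_gives_maximum_achievable_score(self, toy_pfm):
        pwm = build_pwm(toy_pfm)
        s, _ = score_distribution(pwm)
        assert score_threshold(pwm, 1e-12) == pytest.approx(s[-1])

    def test_threshold_tail_bound(self, toy_pfm):
        pwm = build_pwm(toy_pfm)
        t = score_threshold(pwm, 1e-3)
        s, p = score_distribution(pwm)
        assert p[s >= t - 1e-9].sum() <= 1e-3

    def test_bad_p_rejected(self, toy_pfm):
        pwm = build_pwm(toy_pfm)
        with pytest.raises(ValueError):
            score_threshold(pwm, 0.0)


class TestScan:
    def test_planted_consensus_found(self, toy_pfm, rng):
        seq = list(rng.choice(list("ACGT"), size=10_000))
        seq[1000 : 1000 + toy_pfm.width] = list(toy_pfm.consensus)
        genome = Genome({"chr1": "".join(seq)})
        pwm = build_pwm(toy_pfm)
        sites = scan_motifs(genome, pwm, score_threshold(pwm, 1e-4))
        assert any(s.start == 1000 and s.strand == "+" for s in sites)

    def test_palindrome_reported_on_both_strands(self):
        counts = np.full((4, 6), 0.5)
        for j, b in enumerate("GAATTC"):  # EcoRI site, revcomp-palindromic
            counts["ACGT".index(b), j] = 20.0
        pwm = build_pwm(PositionFrequencyMatrix(counts))
        genome = Genome({"chr1": "CCCCGAATTCCCCC"})
        sites = scan_motifs(genome, pwm, score_threshold(pwm, 1e-3))
        strands = {s.strand for s in sites if s.start == 4}
        assert strands == {"+", "-"}

    def test_ambiguous_window_skipped(self, toy_pfm):
        genome = Genome({"chr1": "ACGN" + toy_pfm.consensus[:-4] + "ACGTACGT"})
        pwm = build_pwm(toy_pfm)
        sites = scan_motifs(genome, pwm, pwm.min_score())
        assert all(s.start >= 4 for s in sites)

    def test_reverse_complement_symmetry(self, toy_pfm, rng):
        from atacqc.io import reverse_complement

        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        pwm = build_pwm(toy_pfm)
        t = score_threshold(pwm, 1e-3)
        fwd = scan_motifs(Genome({"c": seq}), pwm, t)
        rev = scan_motifs(Genome({"c": reverse_complement(seq)}), pwm, t)
        n = len(seq)
        mirrored = {(n - s.end, n - s.start, "+-"["+-".index(s.strand) ^ 1])
                    for s in rev}
        assert {(s.start, s.end, s.strand) for s in fwd} == mirrored


class TestIntersectOpen:
    def test_containment_and_complement(self):
        sites = [MotifSite("chr1", 100, 110, "+", 1.0),
                 MotifSite("chr1", 900, 910, "+", 1.0)]
        peaks = HotspotSet("p", [GenomicInterval("chr1", 50, 200)])
        kept = intersect_open(sites, peaks)
        assert [s.start for s in kept] == [100]

    def test_empty_peaks_empty_output(self):
        sites = [MotifSite("chr1", 100, 110, "+", 1.0)]
        assert intersect_open(sites, HotspotSet("p", [])) == []


class TestMappability:
    def test_hand_catalog_acgtacgt(self):
        mask = mappability_mask(Genome({"c": "ACGTACGT"}), k=4)
        arr = mask.unique["c"]
        # ACGT occurs twice forward -> 0 and 4 ambiguous; CGTA/TACG are a
        # revcomp pair -> ambiguous; GTAC is a single-locus palindrome.
        assert list(arr) == [False, False, True, False, False]

    def test_k_longer_than_contig_rejected(self):
        with pytest.raises(ValueError):
            mappability_mask(Genome({"c": "ACGT"}), k=10)

    def test_random_10kb_k50_all_unique(self, tiny_genome):
        mask = mappability_mask(tiny_genome, k=50)
        assert mask.unique["chr1"].all()

    def test_strand_addressing(self):
        mask = MappabilityMask({"c": np.array([True, False, True])}, k=3)
        assert mask.unique_at("c", 0, "+")
        assert not mask.unique_at("c", 0, "-")  # k-mer would start at -2
        assert mask.unique_at("c", 4, "-")  # k-mer [2, 5)
        assert not mask.unique_at("c", 4, "+")


def full_mask(genome):
    return MappabilityMask(
        {c: np.ones(len(s), bool) for c, s in genome.sequences.items()}, k=1
    )


class TestHexamerModel:
    def test_homopolymer_single_hexamer(self):
        genome = Genome({"c": "A" * 200})
        cuts = CutSites({"c": (np.arange(10, 100), np.ones(90, bool))})
        model = hexamer_model(cuts, genome, full_mask(genome))
        assert model.rates[0] == 1.0  # AAAAAA has code 0
        assert (model.rates > 0).sum() == 1

    def test_zero_cuts_rejected(self):
        genome = Genome({"c": "ACGT" * 50})
        with pytest.raises(ValueError):
            hexamer_model(CutSites({}), genome, full_mask(genome))

    def test_planted_model_reproduces_weights(self, tiny_genome, rng):
        bias = np.exp(rng.normal(0, 0.3, 4096))
        mask = mappability_mask(tiny_genome, k=50)
        model = planted_bias_model(bias, tiny_genome, mask)
        w = model.expected_weight()
        present = model.abundance > 0
        ratio = w[present] / bias[present]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)


class TestFootprintProfile:
    def _study(self, factor, n_cuts=200_000, seed=31):
        spec = SimulationSpec(
            seed=seed, n_genes=0, tss_enrichment_factor=1.0,
            motif_consensus="TGACGTCATTG", n_motif_sites=80,
            protection_factor=factor, genome_length=100_000, mito_fraction=0.0,
        )
        genome, genes, truth = make_genome(spec)
        sites = [MotifSite(s["chrom"], s["start"], s["end"], s["strand"], 0.0)
                 for s in truth["motif_sites"]]
        spec.open_regions = [(s.start - 25, s.end + 25) for s in sites]
        cuts = draw_cuts(spec, genome, genes, motif_sites=sites, n_cuts=n_cuts)
        mask = mappability_mask(genome, k=50)
        bias = planted_bias_model(np.ones(4096), genome, mask)
        return footprint_profile(cuts, sites, bias, mask, genome, flank=25)

    def test_unprotected_motif_has_no_depth(self):
        prof = self._study(1.0)
        assert abs(prof.depth) < 0.05

    def test_protection_recovered_and_monotone(self):
        depths = [self._study(f).depth for f in (0.25, 0.5, 1.0)]
        assert depths[0] < depths[1] < depths[2]
        assert depths[0] == pytest.approx(-2.0, abs=0.15)

    def test_depth_invariant_to_downsampling(self, rng):
        spec = SimulationSpec(
            seed=77, n_genes=0, tss_enrichment_factor=1.0,
            motif_consensus="TGACGTCATTG", n_motif_sites=80,
            protection_factor=0.5, genome_length=100_000, mito_fraction=0.0,
        )
        genome, genes, truth = make_genome(spec)
        sites = [MotifSite(s["chrom"], s["start"], s["end"], s["strand"], 0.0)
                 for s in truth["motif_sites"]]
        spec.open_regions = [(s.start - 25, s.end + 25) for s in sites]
        mask = mappability_mask(genome, k=50)
        bias = planted_bias_model(np.ones(4096), genome, mask)
        depths = []
        for n in (400_000, 100_000):
            cuts = draw_cuts(spec, genome, genes, motif_sites=sites, n_cuts=n,
                             rng=np.random.default_rng(5))
            depths.append(
                footprint_profile(cuts, sites, bias, mask, genome, flank=25).depth
            )
        assert depths[0] == pytest.approx(depths[1], abs=0.1)

    def test_no_sites_rejected(self, tiny_genome):
        mask = full_mask(tiny_genome)
        bias = planted_bias_model(np.ones(4096), tiny_genome, mask)
        with pytest.raises(ValueError):
            footprint_profile(CutSites({}), [], bias, mask, tiny_genome)
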