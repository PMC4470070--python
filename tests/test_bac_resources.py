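"""Clone library, fingerprint contigs, genetic bins and marker placement."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import interval_union_length

from haplotile.bac_resources import (
    GeneticBinMap,
    band_overlap,
    contig_build,
    coverage_probability,
    fingerprint_clone,
    fingerprint_library,
    place_markers,
    sample_bac_library,
)
from haplotile.errors import ConfigurationError, InputError
from haplotile.synthetic_genome import (
    DiploidChromosome,
    DivergenceModel,
    RegionSpec,
    Tract,
    derive_haplotypes,
    simulate_reference,
)


class TestCoverageProbability:
    @pytest.mark.parametrize("c,expected,tol", [
        (4.8, 0.9918, 5e-5),       # the library's design depth, "99.2%"
        (0.0, 0.0, 0.0),
        (math.log(2), 0.5, 1e-12),
    ])
    def test_closed_form_values(self, c, expected, tol):
        assert coverage_probability(c) == pytest.approx(expected, abs=tol)

    def test_reported_percentage_rounds_to_99_2(self):
        assert round(100 * coverage_probability(4.8), 1) == 99.2

    def test_negative_equivalents_rejected(self):
        with pytest.raises(ConfigurationError):
            coverage_probability(-1.0)

    @given(st.floats(0, 30), st.floats(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_bounded(self, c1, c2):
        p1, p2 = coverage_probability(c1), coverage_probability(c2)
        assert 0 <= p1 < 1
        if c1 < c2:
            assert p1 < p2


class TestLibrary:
    def test_zero_sd_gives_constant_lengths(self, small_diploid):
        clones = sample_bac_library(small_diploid, mean_len=50_000, len_sd=0,
                                    equivalents_per_hap=1.0, seed=1)
        assert {c.length for c in clones} == {50_000}

    def test_mean_length_matches_design(self):
        d = DiploidChromosome.simulate(total_length=2_000_000, seed=2)
        clones = sample_bac_library(d, equivalents_per_hap=20.0, seed=2)
        assert len(clones) >= 500
        mean = np.mean([c.length for c in clones])
        assert mean == pytest.approx(122_651, rel=0.02)
        assert all(14_260 <= c.length <= 216_437 for c in clones)

    def test_bes_are_exact_clone_ends(self, small_diploid):
        clones = sample_bac_library(small_diploid, mean_len=40_000, len_sd=5_000,
                                    equivalents_per_hap=0.5, seed=3)
        for c in clones[:10]:
            assert np.array_equal(c.bes_left, c.sequence[:500])
            assert np.array_equal(c.bes_right, c.sequence[-500:])
            hap = small_diploid.haplotype(c.haplotype_of_origin)
            assert np.array_equal(c.sequence, hap[c.start:c.end])

    def test_observed_coverage_matches_clarke_carbon(self, small_diploid):
        # union of true clone intervals vs 1 - e^{-c}, averaged over seeds;
        # clones are kept small relative to the chromosome because the
        # random-library coverage law is the L << G limit (with large L/G
        # the uncovered mass concentrates at the chromosome ends)
        expected = coverage_probability(4.8)
        fractions = []
        for seed in range(6):
            clones = sample_bac_library(small_diploid, seed=seed, mean_len=5_000,
                                        len_sd=1_000, min_len=2_000, max_len=10_000)
            for hap in (0, 1):
                n = len(small_diploid.haplotype(hap))
                ivs = [c.true_interval for c in clones if c.haplotype_of_origin == hap]
                fractions.append(interval_union_length(ivs) / n)
        assert np.mean(fractions) == pytest.approx(expected, abs=0.01)

    def test_mean_length_must_fit_haplotype(self, small_diploid):
        with pytest.raises(ConfigurationError):
            sample_bac_library(small_diploid, mean_len=10_000_000, seed=0)


class TestFingerprints:
    def test_identical_intervals_identical_fingerprints_one_contig(self, small_diploid):
        clones = sample_bac_library(small_diploid, mean_len=60_000, len_sd=0,
                                    equivalents_per_hap=0.8, seed=4)
        a = clones[0]
        b = type(a)(id="DUP", haplotype_of_origin=a.haplotype_of_origin,
                    start=a.start, end=a.end, sequence=a.sequence,
                    bes_left=a.bes_left, bes_right=a.bes_right)
        fps = fingerprint_library([a, b])
        assert np.array_equal(fps[a.id].bands, fps["DUP"].bands)
        contigs = contig_build([a, b], fps)
        assert len(contigs) == 1 and set(contigs[0].clone_ids) == {a.id, "DUP"}

    def test_non_overlapping_clones_rarely_link(self, small_diploid):
        clones = sample_bac_library(small_diploid, mean_len=60_000, len_sd=0,
                                    equivalents_per_hap=2.0, seed=5)
        fps = fingerprint_library(clones)
        pairs = checked = 0
        for i in range(len(clones)):
            for j in range(i + 1, len(clones)):
                a, b = clones[i], clones[j]
                # exclude pairs near the same genomic position on either
                # homologue: allelic clones in low-divergence tracts share
                # bands by design (that is how mixed contigs arise)
                if min(a.end, b.end) - max(a.start, b.start) > -20_000:
                    continue
                smaller = min(fps[a.id].n_bands, fps[b.id].n_bands)
                if smaller == 0:
                    continue
                checked += 1
                if band_overlap(fps[a.id].bands, fps[b.id].bands) >= 0.6 * smaller:
                    pairs += 1
        assert checked > 300
        assert pairs / checked < 0.01

    def test_contig_membership_partitions_library(self, small_diploid):
        clones = sample_bac_library(small_diploid, mean_len=60_000, len_sd=10_000,
                                    min_len=20_000, max_len=120_000,
                                    equivalents_per_hap=2.0, seed=6)
        fps = fingerprint_library(clones)
        contigs = contig_build(clones, fps)
        members = [cid for ctg in contigs for cid in ctg.clone_ids]
        assert sorted(members) == sorted(c.id for c in clones)

    def test_empty_library_rejected(self):
        with pytest.raises(InputError):
            contig_build([], {})

    def test_digest_needs_a_motif(self, small_diploid):
        clones = sample_bac_library(small_diploid, mean_len=40_000, len_sd=0,
                                    equivalents_per_hap=0.2, seed=7)
        with pytest.raises(InputError):
            fingerprint_clone(clones[0], motifs=())


class TestBinMap:
    def test_heterochromatin_collapses_to_single_bin(self, small_diploid):
        bm = GeneticBinMap.from_regions(small_diploid.regions)
        het = [r for r in small_diploid.regions
               if r.region_class in ("het_border", "central_het")]
        lo, hi = min(r.start for r in het), max(r.end for r in het)
        for pos in np.linspace(lo, hi - 1, 20).astype(int):
            assert bm.bin_of(int(pos)) == 46
        assert bm.bin_of(0) == 1
        assert bm.bin_of(bm.total_length - 1) == 78
        # monotone along the chromosome
        bins = [bm.bin_of(int(p)) for p in np.linspace(0, bm.total_length - 1, 200)]
        assert all(b1 <= b2 for b1, b2 in zip(bins, bins[1:]))

    def test_out_of_range_position_rejected(self, small_diploid):
        bm = GeneticBinMap.from_regions(small_diploid.regions)
        with pytest.raises(InputError):
            bm.bin_of(-1)


class TestMarkers:
    def test_fully_homozygous_chromosome_yields_no_markers(self):
        ref, _ = simulate_reference(120_000, seed=8)
        regions = [RegionSpec("north_euchromatin", "euchromatin", 0, 120_000,
                              [Tract("homozygous", 0, 120_000)])]
        model = DivergenceModel(small_indel_rate=0.0)
        h0, h1, truth = derive_haplotypes(ref, regions, model, seed=8)
        bm = GeneticBinMap(binT=78, het_bin=46, het_start=60_000, het_end=60_001,
                           total_length=120_000)
        d = DiploidChromosome(ref, h0, h1, regions, truth)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            markers = place_markers(d, truth, 1e-3, bm, seed=8)
        assert markers == []
        assert any("zero markers" in str(w.message) for w in caught)

    def test_central_het_markers_all_carry_bin_46(self, small_diploid):
        bm = GeneticBinMap.from_regions(small_diploid.regions)
        markers = place_markers(small_diploid, small_diploid.truth, 5e-4, bm, seed=9)
        central = next(r for r in small_diploid.regions if r.region_class == "central_het")
        in_het = 0
        for m in markers:
            tract = small_diploid.truth.hap_tract_of(m.position, m.phase)
            if tract and tract.region == central.name:
                in_het += 1
                assert m.bin == 46
        assert in_het > 0

    def test_expected_marker_count_scales_with_density(self, small_diploid):
        bm = GeneticBinMap.from_regions(small_diploid.regions)
        truth = small_diploid.truth
        n_sites = sum(len(truth.polymorphic_sites[h]) for h in (0, 1))
        n_interval = sum(hi - lo for h in (0, 1) for lo, hi in truth.polymorphic_intervals[h])
        density = 2e-4
        expected = density * (n_sites + n_interval)
        counts = [len(place_markers(small_diploid, truth, density, bm, seed=s))
                  for s in range(12)]
        # Poisson-scale check: mean within 4 standard errors
        se = math.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_phase_exclusivity(self, small_diploid):
        bm = GeneticBinMap.from_regions(small_diploid.regions)
        clones = sample_bac_library(small_diploid, mean_len=60_000, len_sd=0,
                                    equivalents_per_hap=1.0, seed=10)
        markers = place_markers(small_diploid, small_diploid.truth, 3e-4, bm,
                                seed=10, clones=clones)
        by_id = {c.id: c for c in clones}
        for m in markers:
            for cid in m.carrier_clone_ids:
                assert by_id[cid].haplotype_of_origin == m.phase

    def test_zero_density_rejected(self, small_diploid):
        bm = GeneticBinMap.from_regions(small_diploid.regions)
        with pytest.raises(ConfigurationError):
            place_markers(small_diploid, small_diploid.truth, 0.0, bm)
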