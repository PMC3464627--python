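import numpy as np
import pandas as pd
import pytest

from helpers import interval_mask, pearson_textbook
from mnasetools import synth, tracks
from mnasetools.genome import GenomeSizes
from mnasetools.tracks import (
    CoverageTrack,
    NucleosomeReference,
    correlation_histogram,
    coverage_from_fragments,
    dissimilar_regions,
    genome_correlation,
    linker_class_profiles,
    standardize_track,
    window_correlations,
)


def noise_track(genome, rng, bin_bp=10, loc=10.0):
    return CoverageTrack(
        genome=genome,
        bin_bp=bin_bp,
        data={
            name: rng.poisson(loc, -(-length // bin_bp)).astype(float)
            for name, length in genome
        },
    )


class TestCoverageFromFragments:
    def test_single_fragment_15_bins(self, small_genome):
        track = coverage_from_fragments(
            [("chrI", 1000, 1150)], small_genome, bin_bp=10
        )
        arr = track.data["chrI"]
        assert np.all(arr[100:115] == 1.0)
        assert arr[99] == 0 and arr[115] == 0

    def test_empty_input_zero_track(self, small_genome):
        track = coverage_from_fragments([], small_genome)
        assert track.total == 0.0

    def test_mass_conservation(self, small_genome):
        rng = np.random.default_rng(0)
        frags = []
        for _ in range(300):
            start = int(rng.integers(0, 90_000))
            frags.append(("chrI", start, start + int(rng.integers(50, 400))))
        track = coverage_from_fragments(frags, small_genome, bin_bp=10)
        mass = sum(track.data[c].sum() * 10 for c in track.genome.names)
        expected = sum(e - s for _, s, e in frags)
        assert mass == pytest.approx(expected)

    def test_unknown_chromosome_listed(self, small_genome):
        with pytest.raises(ValueError, match="chrX"):
            coverage_from_fragments([("chrX", 0, 100)], small_genome)

    def test_single_end_extension(self, small_genome):
        track = coverage_from_fragments(
            [("chrI", 1000, 1036)], small_genome, bin_bp=1, extend_to=147
        )
        assert track.data["chrI"][1000:1147].sum() == 147


class TestStandardize:
    def test_total_and_composition(self, small_genome):
        rng = np.random.default_rng(1)
        t = noise_track(small_genome, rng)
        s1 = standardize_track(t, 5000.0)
        assert s1.total == pytest.approx(5000.0)
        s2 = standardize_track(s1, 5000.0)
        assert np.allclose(s1.data["chrI"], s2.data["chrI"])

    def test_zero_total_error(self, small_genome):
        t = coverage_from_fragments([], small_genome)
        with pytest.raises(ValueError):
            standardize_track(t)

    def test_correlation_unchanged(self, small_genome):
        rng = np.random.default_rng(2)
        a, b = noise_track(small_genome, rng), noise_track(small_genome, rng)
        r0 = genome_correlation(a, b, resolution_bp=10)
        r1 = genome_correlation(
            standardize_track(a, 99.0), standardize_track(b, 123.0), resolution_bp=10
        )
        assert r1 == pytest.approx(r0, abs=1e-12)


class TestWindowCorrelations:
    def test_self_correlation_all_one(self, small_genome):
        t = noise_track(small_genome, np.random.default_rng(3))
        wcs = window_correlations(t, t, window_bp=1000)
        assert np.allclose(wcs.r[wcs.defined], 1.0)
        assert wcs.defined.all()

    def test_white_noise_mean_near_zero(self, small_genome):
        rng = np.random.default_rng(4)
        a, b = noise_track(small_genome, rng), noise_track(small_genome, rng)
        wcs = window_correlations(a, b, window_bp=1000)
        n, w = len(wcs.r), 100
        assert abs(np.nanmean(wcs.r)) < 3 / np.sqrt(n * w)

    def test_toy_windows_match_textbook(self):
        genome = GenomeSizes([("c", 40)])
        x = np.array([1.0, 5, 2, 8, 1, 9, 4, 4])
        y = np.array([2.0, 6, 1, 9, 3, 7, 5, 2])
        a = CoverageTrack(genome=genome, bin_bp=5, data={"c": x})
        b = CoverageTrack(genome=genome, bin_bp=5, data={"c": y})
        wcs = window_correlations(a, b, window_bp=20)
        assert wcs.r[0] == pytest.approx(pearson_textbook(x[:4], y[:4]), abs=1e-12)
        assert wcs.r[1] == pytest.approx(pearson_textbook(x[4:], y[4:]), abs=1e-12)

    def test_naive_recomputation_100_random_windows(self, small_genome):
        rng = np.random.default_rng(5)
        a, b = noise_track(small_genome, rng), noise_track(small_genome, rng)
        wcs = window_correlations(a, b, window_bp=1000, step_bp=10)
        df = wcs.windows
        idx = rng.choice(len(df), 100, replace=False)
        for i in idx:
            chrom, start, end, r = df.iloc[i]
            lo, hi = int(start) // 10, int(end) // 10
            naive = pearson_textbook(a.data[chrom][lo:hi], b.data[chrom][lo:hi])
            assert r == pytest.approx(naive, abs=1e-10)

    def test_affine_invariance(self, small_genome):
        rng = np.random.default_rng(6)
        a, b = noise_track(small_genome, rng), noise_track(small_genome, rng)
        b2 = CoverageTrack(
            genome=small_genome,
            bin_bp=10,
            data={k: 3.1 * v + 7.0 for k, v in b.data.items()},
        )
        r1 = window_correlations(a, b, window_bp=1000).r
        r2 = window_correlations(a, b2, window_bp=1000).r
        assert np.allclose(r1, r2, atol=1e-10)

    def test_zero_variance_flagged(self):
        genome = GenomeSizes([("c", 100)])
        a = CoverageTrack(genome=genome, bin_bp=10, data={"c": np.ones(10)})
        b = CoverageTrack(
            genome=genome, bin_bp=10, data={"c": np.arange(10, dtype=float)}
        )
        wcs = window_correlations(a, b, window_bp=100)
        assert np.isnan(wcs.r[0])

    def test_incompatible_tracks_error(self, small_genome):
        t = noise_track(small_genome, np.random.default_rng(7))
        other = GenomeSizes([("chrZ", 1000)])
        u = CoverageTrack(genome=other, bin_bp=10, data={"chrZ": np.ones(100)})
        with pytest.raises(ValueError):
            window_correlations(t, u)


class TestHistogramAndGenomeR:
    def test_all_ones_fraction(self, small_genome):
        t = noise_track(small_genome, np.random.default_rng(8))
        wcs = window_correlations(t, t, window_bp=1000)
        hist = correlation_histogram(wcs)
        assert hist["fraction_gt_0.9"] == 1.0
        assert hist["fraction_lt_0.5"] == 0.0
        assert hist["counts"].sum() == hist["n_defined"]

    def test_genome_correlation_identity_and_sign(self, small_genome):
        rng = np.random.default_rng(9)
        t = noise_track(small_genome, rng)
        assert genome_correlation(t, t) == pytest.approx(1.0)
        reversed_ = CoverageTrack(
            genome=small_genome,
            bin_bp=10,
            data={k: 2 * v.mean() - v for k, v in t.data.items()},
        )
        assert genome_correlation(t, reversed_) < 0

    def test_equals_single_whole_genome_window(self):
        genome = GenomeSizes([("c", 10_000)])
        rng = np.random.default_rng(10)
        a = CoverageTrack(genome=genome, bin_bp=100,
                          data={"c": rng.poisson(20, 100).astype(float)})
        b = CoverageTrack(genome=genome, bin_bp=100,
                          data={"c": rng.poisson(20, 100).astype(float)})
        wcs = window_correlations(a, b, window_bp=10_000)
        assert genome_correlation(a, b, resolution_bp=100) == pytest.approx(
            wcs.r[0], abs=1e-12
        )


def planted_pair(genome, plants, seed, depth=50.0):
    spec = synth.SyntheticTrackSpec(genome=genome, plants=plants, seed=seed,
                                    depth=depth)
    a, b, truth = synth.synth_track_pair(spec)
    return standardize_track(a), standardize_track(b), truth


class TestDissimilarRegions:
    def test_identical_tracks_empty(self, small_genome):
        t = noise_track(small_genome, np.random.default_rng(11))
        assert len(dissimilar_regions(t, t)) == 0

    def test_single_plant_recovered(self):
        genome = GenomeSizes([("chrI", 200_000)])
        plants = [("chrI", 80_000, 83_000)]
        a, b, truth = planted_pair(genome, plants, seed=13)
        dis = dissimilar_regions(a, b)
        assert len(dis) == 1
        tm = interval_mask(truth, genome)
        dm = interval_mask(dis.regions, genome)
        # >= 80% of the plant recovered; the union merging rule may
        # overhang each edge by at most one window
        assert (tm & dm).sum() / tm.sum() >= 0.8
        assert (dm & ~tm).sum() <= 2 * dis.window_bp

    def test_separated_plants_stay_separate(self):
        genome = GenomeSizes([("chrI", 200_000)])
        plants = [("chrI", 50_000, 53_000), ("chrI", 120_000, 123_000)]
        a, b, truth = planted_pair(genome, plants, seed=14)
        dis = dissimilar_regions(a, b)
        assert len(dis) == 2

    def test_step_refinement_keeps_long_plants(self):
        """Halving the step never loses a plant >= 3 windows long."""
        genome = GenomeSizes([("chrI", 150_000)])
        plants = [("chrI", 60_000, 63_000)]
        a, b, truth = planted_pair(genome, plants, seed=15)
        tm = interval_mask(truth, genome)
        for step in (40, 20, 10):
            dis = dissimilar_regions(a, b, step_bp=step)
            dm = interval_mask(dis.regions, genome)
            assert (tm & dm).sum() / tm.sum() >= 0.8

    def test_determinism(self):
        genome = GenomeSizes([("chrI", 100_000)])
        a, b, _ = planted_pair(genome, [("chrI", 40_000, 43_000)], seed=16)
        d1 = dissimilar_regions(a, b)
        d2 = dissimilar_regions(a, b)
        pd.testing.assert_frame_equal(d1.regions, d2.regions)


class TestLinkerClassProfiles:
    def make_reference(self):
        # chain at 2000: linkers n1-(15)-n2-(15)-n3-(100)-n4-(50)-n5-(300)-n6
        starts = [2000]
        for gap in (15, 15, 100, 50, 300):
            starts.append(starts[-1] + 147 + gap)
        df = pd.DataFrame(
            {"chrom": "chrI", "start": starts, "end": [s + 147 for s in starts]}
        )
        return NucleosomeReference(positions=df)

    def test_classification_rule(self):
        ref = self.make_reference()
        ann = ref.annotated
        # n2 has 15/15 -> both normal; n4 has 100/50 -> both long;
        # n5 has a 300-bp right gap -> 'other' side
        assert ann.loc[1, "left_class"] == "normal"
        assert ann.loc[1, "right_class"] == "normal"
        assert ann.loc[3, "left_class"] == "long"
        assert ann.loc[3, "right_class"] == "long"
        assert ann.loc[4, "right_class"] == "other"
        # n3: 15/100 -> mixed; boundary nucleosomes have an 'other' side
        assert {ann.loc[2, "left_class"], ann.loc[2, "right_class"]} == {
            "normal", "long"}
        assert ann.loc[0, "left_class"] == "other"
        assert len(ref.both_class("normal")) == 1
        assert len(ref.both_class("long")) == 1

    def test_uniform_track_flat_profiles(self, small_genome):
        ref = self.make_reference()
        t = CoverageTrack(
            genome=small_genome,
            bin_bp=10,
            data={n: np.full(-(-l // 10), 3.0) for n, l in small_genome},
        )
        prof = linker_class_profiles(t, ref, flank_bp=100)
        assert np.allclose(prof["normal"], 3.0)
        assert np.allclose(prof["long"], 3.0)

    def test_planted_contrast(self, small_genome):
        ref = self.make_reference()
        data = {n: np.full(-(-l // 10), 1.0) for n, l in small_genome}
        long_nuc = ref.both_class("long").iloc[0]
        lo, hi = int(long_nuc["start"]) // 10, int(long_nuc["end"]) // 10
        data["chrI"][lo:hi] = 5.0
        t = CoverageTrack(genome=small_genome, bin_bp=10, data=data)
        prof = linker_class_profiles(t, ref, flank_bp=50)
        mid = len(prof["long"]) // 2
        assert prof["long"][mid] > prof["normal"][mid]
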