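"""Tests for origin-aligned signals and occupancy matrices."""

import numpy as np
import pandas as pd
import pytest

from oritools.genome import CoverageTrack, GenomeAnnotation, OriginAnnotation
from oritools import footprints as fp
from oritools import simulate as sim

from conftest import make_track
from oracles import (naive_class_signal, naive_occupancy_total,
                     naive_scaled_fraction, naive_stability_ratio)


def frame(records):
    return pd.DataFrame(records, columns=["chrom", "start", "end"])


class TestAggregateSignalProfile:
    def test_constant_track_has_flat_mean_and_zero_interval(self, small_genome,
                                                            small_origins):
        track = CoverageTrack.from_constant(small_genome, 3.5)
        prof = fp.aggregate_signal_profile(track, small_origins, 200)
        assert np.allclose(prof.mean, 3.5)
        assert np.allclose(prof.ci_halfwidth, 0.0)

    def test_strand_flip_invariance_over_symmetric_peak(self, small_genome):
        track = make_track(
            small_genome,
            lambda c, x: 1.0 + np.exp(-0.5 * ((x - 10_000) / 50.0) ** 2))
        both = [OriginAnnotation("p", "chrI", 10_000, "+"),
                OriginAnnotation("m", "chrI", 10_000, "-")]
        plus_only = [OriginAnnotation("p1", "chrI", 10_000, "+"),
                     OriginAnnotation("p2", "chrI", 10_000, "+")]
        a = fp.aggregate_signal_profile(track, both, 300)
        b = fp.aggregate_signal_profile(track, plus_only, 300)
        assert np.allclose(a.mean, b.mean)

    def test_minus_strand_window_reads_t_rich_left_to_right(self, small_genome):
        track = make_track(small_genome,
                           lambda c, x: x.astype(float) if c == "chrI" else 0 * x)
        origin = OriginAnnotation("m", "chrI", 10_000, "-")
        prof = fp.aggregate_signal_profile(track, [origin], 5)
        # rel +1 is one bp 3' on the T-rich strand = genomic 9_999
        assert prof.mean[prof.rel_positions.tolist().index(1)] == 9_999

    def test_recovers_planted_chip_peak_center(self, small_genome):
        origins = [OriginAnnotation(f"o{i}", "chrI", 3_000 + 500 * i,
                                    "+" if i % 2 else "-")
                   for i in range(50)]
        ip, inp = sim.simulate_signal_tracks(small_genome, origins,
                                             peak_height=4.0, peak_sd=60.0,
                                             depth=50.0, seed=4)
        prof = fp.aggregate_signal_profile(fp.normalize_track(ip, inp),
                                           origins, 250)
        peak = prof.rel_positions[np.nanargmax(prof.mean)]
        assert abs(peak) <= 10

    def test_empty_group_rejected(self, small_genome):
        with pytest.raises(ValueError):
            fp.aggregate_signal_profile(
                CoverageTrack.from_constant(small_genome, 1.0), [], 100)


class TestNormalizeTrack:
    def test_identical_tracks_normalize_to_unit_ratio(self, small_genome, rng):
        track = make_track(small_genome,
                           lambda c, x: rng.poisson(30, x.size) + 1.0)
        out = fp.normalize_track(track, track)
        for _, arr in out.items():
            assert np.allclose(arr[np.isfinite(arr)], 1.0)

    def test_ip_depth_cancels(self, small_genome, rng):
        ip = make_track(small_genome,
                        lambda c, x: rng.poisson(30, x.size) + 1.0)
        inp = make_track(small_genome,
                         lambda c, x: rng.poisson(25, x.size) + 1.0)
        doubled = CoverageTrack(small_genome,
                                {c: 2.0 * v for c, v in ip.items()})
        a = fp.normalize_track(ip, inp)
        b = fp.normalize_track(doubled, inp)
        for chrom in small_genome.names:
            assert np.allclose(a[chrom], b[chrom], equal_nan=True)

    def test_planted_enrichment_region_stands_out_fourfold(self, small_genome):
        def ip_fn(c, x):
            base = np.full(x.size, 100.0)
            if c == "chrI":
                base[5_000:6_000] *= 4.0
            return base
        ratio = fp.normalize_track(make_track(small_genome, ip_fn),
                                   CoverageTrack.from_constant(small_genome,
                                                               100.0))
        inside = np.nanmean(ratio["chrI"][5_000:6_000])
        outside = np.nanmean(ratio["chrI"][:5_000])
        assert inside / outside == pytest.approx(4.0, rel=1e-6)


class TestOccupancyMatrix:
    def test_single_fragment_paints_one_row(self):
        loci = [OriginAnnotation("o", "c", 1_000, "+")]
        frags = frame([("c", 900, 1_050)])  # length 150, inside the window
        mat = fp.build_occupancy_matrix(frags, loci, 500)
        row = mat.values[mat.lengths.tolist().index(150)]
        assert row.sum() == 150
        assert np.all(np.flatnonzero(row) == np.arange(900, 1_050) - 1_000 + 500)
        assert mat.values.sum() == 150

    def test_grand_total_matches_quadratic_overlap_oracle(self, rng):
        loci = [OriginAnnotation(f"o{i}", "c", int(p), "+" if i % 2 else "-")
                for i, p in enumerate((700, 1_500, 2_600))]
        frags = []
        for _ in range(400):
            s = int(rng.integers(0, 3_000))
            frags.append(("c", s, s + int(rng.integers(60, 190))))
        span = 300
        mat = fp.build_occupancy_matrix(frame(frags), loci, span)
        windows = [(o.chrom, o.orc_start - span, o.orc_start + span)
                   for o in loci]
        assert mat.values.sum() == naive_occupancy_total(frags, windows)

    def test_translation_invariance(self, rng):
        frags = [("c", int(s), int(s) + 120)
                 for s in rng.integers(100, 2_000, 200)]
        loci = [OriginAnnotation("o", "c", 1_200, "+")]
        shifted_frags = [("c", s + 1_000, e + 1_000) for _, s, e in frags]
        shifted_loci = [OriginAnnotation("o", "c", 2_200, "+")]
        genome_pad = 5_000
        a = fp.build_occupancy_matrix(frame(frags), loci, 400)
        b = fp.build_occupancy_matrix(frame(shifted_frags), shifted_loci, 400)
        np.testing.assert_array_equal(a.values, b.values)

    def test_strand_mirroring_is_exact(self, rng):
        """Mirrored fragments around a minus-strand locus reproduce the
        plus-strand matrix exactly."""
        center = 5_000
        frags, mirrored = [], []
        for _ in range(300):
            s = int(rng.integers(4_200, 5_700))
            L = int(rng.integers(60, 190))
            frags.append(("c", s, s + L))
            # mirror around the anchor: position p -> 2*center - p
            mirrored.append(("c", 2 * center - (s + L - 1), 2 * center - s + 1))
        plus = fp.build_occupancy_matrix(
            frame(frags), [OriginAnnotation("o", "c", center, "+")], 600)
        minus = fp.build_occupancy_matrix(
            frame(mirrored), [OriginAnnotation("o", "c", center, "-")], 600)
        np.testing.assert_array_equal(plus.values, minus.values)

    def test_frequency_form_sums_to_one(self, rng):
        frags = frame([("c", int(s), int(s) + 140)
                       for s in rng.integers(0, 2_000, 100)])
        mat = fp.build_occupancy_matrix(frags,
                                        [OriginAnnotation("o", "c", 1_000, "+")],
                                        500).to_frequency()
        assert mat.values.sum() == pytest.approx(1.0)

    def test_midpoint_mode_counts_each_fragment_once(self):
        loci = [OriginAnnotation("o", "c", 1_000, "+")]
        frags = frame([("c", 900, 1_050), ("c", 980, 1_120)])
        mat = fp.build_occupancy_matrix(frags, loci, 500, midpoint_only=True)
        assert mat.values.sum() == 2


class TestClassSignals:
    def make_matrix(self, rng):
        lengths = np.arange(50, 201)
        values = rng.poisson(3.0, (lengths.size, 41)).astype(float)
        return fp.OccupancyMatrix(lengths, np.arange(-20, 21), values)

    def test_single_populated_row_defines_the_class_signal(self):
        lengths = np.arange(50, 201)
        values = np.zeros((lengths.size, 11))
        values[lengths.tolist().index(150)] = np.arange(11.0)
        mat = fp.OccupancyMatrix(lengths, np.arange(-5, 6), values)
        np.testing.assert_array_equal(
            fp.class_signal(mat, fp.NUCLEOSOME_STABILITY), np.arange(11.0))
        np.testing.assert_array_equal(
            fp.class_signal(mat, fp.SUBNUCLEOSOME_STABILITY), np.zeros(11))

    def test_matches_explicit_row_summation(self, rng):
        mat = self.make_matrix(rng)
        for spec in (fp.NUCLEOSOME_STABILITY, fp.SUBNUCLEOSOME_STABILITY,
                     fp.NUCLEOSOME_SCALED, fp.ORC_CDC6_SCALED):
            ref = naive_class_signal(mat.values, list(mat.lengths),
                                     spec.lo, spec.hi)
            np.testing.assert_allclose(fp.class_signal(mat, spec), ref)

    def test_disjoint_class_outside_matrix_rejected(self):
        mat = fp.OccupancyMatrix(np.arange(50, 101), np.arange(-2, 3),
                                 np.zeros((51, 5)))
        with pytest.raises(ValueError):
            fp.class_signal(mat, fp.NUCLEOSOME_STABILITY)


class TestStabilityRatio:
    def make_matrix(self, rng, scale=1.0):
        lengths = np.arange(100, 181)
        vals = scale * rng.poisson(20.0, (lengths.size, 31)).astype(float)
        return fp.OccupancyMatrix(lengths, np.arange(-15, 16), vals)

    def test_identical_genotypes_give_unit_ratio(self, rng):
        mat = self.make_matrix(rng)
        out = fp.stability_ratio(mat, mat)
        assert np.allclose(out[np.isfinite(out)], 1.0)

    def test_worked_arithmetic_example(self):
        lengths = np.arange(100, 181)
        wt = np.zeros((lengths.size, 1))
        mut = np.zeros((lengths.size, 1))
        wt[lengths.tolist().index(150), 0] = 100  # nucleosome class
        wt[lengths.tolist().index(130), 0] = 50  # subnucleosome class
        mut[lengths.tolist().index(150), 0] = 80
        mut[lengths.tolist().index(130), 0] = 80
        rel = np.array([0])
        out = fp.stability_ratio(
            fp.OccupancyMatrix(lengths, rel, mut),
            fp.OccupancyMatrix(lengths, rel, wt), pseudocount=0.0)
        assert out[0] == pytest.approx(0.5)

    def test_scale_invariance_without_pseudocount(self, rng):
        wt = self.make_matrix(rng)
        mut = self.make_matrix(rng)
        scaled = fp.OccupancyMatrix(mut.lengths, mut.rel_positions,
                                    7.0 * mut.values)
        a = fp.stability_ratio(mut, wt, pseudocount=0.0)
        b = fp.stability_ratio(scaled, wt, pseudocount=0.0)
        assert np.allclose(a, b, equal_nan=True)

    def test_matches_naive_loop_computation(self, rng):
        wt, mut = self.make_matrix(rng), self.make_matrix(rng)
        out = fp.stability_ratio(mut, wt, pseudocount=1.0)
        ref = naive_stability_ratio(
            naive_class_signal(mut.values, list(mut.lengths), 142, 162),
            naive_class_signal(mut.values, list(mut.lengths), 121, 141),
            naive_class_signal(wt.values, list(wt.lengths), 142, 162),
            naive_class_signal(wt.values, list(wt.lengths), 121, 141), 1.0)
        np.testing.assert_allclose(out, ref, equal_nan=True)

    def test_negative_pseudocount_rejected(self, rng):
        mat = self.make_matrix(rng)
        with pytest.raises(ValueError):
            fp.stability_ratio(mat, mat, pseudocount=-1.0)


class TestScaledFractionSignal:
    def test_pure_class_positions_reach_raw_fraction_one(self):
        lengths = np.arange(60, 181)
        vals = np.zeros((lengths.size, 3))
        vals[lengths.tolist().index(150), 0] = 10  # pure nucleosome column
        vals[lengths.tolist().index(80), 1] = 10  # pure ORC column
        vals[lengths.tolist().index(150), 2] = 5
        vals[lengths.tolist().index(80), 2] = 5
        mat = fp.OccupancyMatrix(lengths, np.arange(3), vals)
        out = fp.scaled_fraction_signal(mat, fp.NUCLEOSOME_SCALED)
        assert out[0] == 1.0 and out[1] == 0.0

    def test_minmax_bounds_attained(self, rng):
        lengths = np.arange(60, 181)
        vals = rng.poisson(5.0, (lengths.size, 21)).astype(float)
        mat = fp.OccupancyMatrix(lengths, np.arange(-10, 11), vals)
        out = fp.scaled_fraction_signal(mat, fp.ORC_CDC6_SCALED)
        finite = out[np.isfinite(out)]
        assert finite.min() == 0.0 and finite.max() == 1.0

    def test_matches_naive_loop_computation(self, rng):
        lengths = np.arange(60, 181)
        vals = rng.poisson(4.0, (lengths.size, 15)).astype(float)
        mat = fp.OccupancyMatrix(lengths, np.arange(15), vals)
        out = fp.scaled_fraction_signal(mat, fp.NUCLEOSOME_SCALED)
        ref = naive_scaled_fraction(vals, list(lengths), 137, 157)
        np.testing.assert_allclose(out, ref, equal_nan=True)

    def test_planted_orc_footprint_peaks_on_the_site(self):
        genome, origins, config = sim.g1_chromatin_scenario(seed=5)
        frags = sim.simulate_fragment_experiment(genome, origins, config,
                                                 60_000)
        mat = fp.build_occupancy_matrix(frags, origins, 400)
        orc = fp.scaled_fraction_signal(mat, fp.ORC_CDC6_SCALED)
        peak = mat.rel_positions[np.nanargmax(orc)]
        assert abs(peak) <= 30
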