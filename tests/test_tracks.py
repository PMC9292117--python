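import numpy as np
import pytest

from ndrchip.io import Feature, FeatureTable, SampleMeta, make_fragment_set
from ndrchip.tracks import (DyadParams, OccupancyTrack, compute_coverage,
                            compute_dyad_density, correct_background,
                            difference_track, mask_intervals, merge_replicates,
                            moving_average, normalize_per_chromosome)

from conftest import random_fragments


def brute_force_coverage(fragments, layout):
    out = {name: np.zeros(length) for name, length in
           zip(layout.names, layout.lengths)}
    for c, s, e in zip(fragments.chrom, fragments.start, fragments.end):
        for b in range(s, e):
            out[c][b] += 1
    return out


class TestCoverage:
    def test_single_fragment(self, layout):
        fs = make_fragment_set(layout, ["chrI"], [10], [20])
        track = compute_coverage(fs)
        assert track.data["chrI"][10:20].tolist() == [1.0] * 10
        assert track.data["chrI"].sum() == 10 and track.mass == 10

    def test_overlapping_fragments(self, layout):
        fs = make_fragment_set(layout, ["chrI"] * 2, [10, 15], [20, 25])
        cov = compute_coverage(fs).data["chrI"]
        assert np.array_equal(cov[10:15], np.ones(5))
        assert np.array_equal(cov[15:20], np.full(5, 2.0))
        assert np.array_equal(cov[20:25], np.ones(5))

    def test_matches_brute_force(self, layout, rng):
        fs = random_fragments(layout, rng, n=200)
        track = compute_coverage(fs)
        expected = brute_force_coverage(fs, layout)
        for name in layout.names:
            assert np.array_equal(track.data[name], expected[name])

    def test_mass_equals_total_fragment_length(self, layout, rng):
        fs = random_fragments(layout, rng, n=500)
        assert compute_coverage(fs).mass == fs.lengths.sum()

    def test_empty_set_rejected(self, layout):
        fs = make_fragment_set(layout, [], [], [])
        with pytest.raises(ValueError):
            compute_coverage(fs)


class TestDyadDensity:
    def test_midpoint_placement(self, layout):
        fs = make_fragment_set(layout, ["chrI"], [100], [250],
                               SampleMeta(prep="mnase"))
        track = compute_dyad_density(fs)
        assert track.data["chrI"][175] == 1.0 and track.mass == 1.0

    def test_short_fragment_contributes_nothing(self, layout):
        fs = make_fragment_set(layout, ["chrI"], [100], [200],
                               SampleMeta(prep="mnase"))
        assert compute_dyad_density(fs).mass == 0.0

    def test_mass_equals_in_range_count(self, layout, rng):
        fs = random_fragments(layout, rng, n=300, min_len=100, max_len=250,
                              meta=SampleMeta(prep="mnase"))
        lengths = fs.lengths
        expected = int(((lengths >= 125) & (lengths <= 175)).sum())
        assert compute_dyad_density(fs).mass == expected

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DyadParams(min_length=0)
        with pytest.raises(ValueError):
            DyadParams(smoothing_span=30)

    def test_non_mnase_warns(self, layout):
        fs = make_fragment_set(layout, ["chrI"], [100], [250])
        with pytest.warns(UserWarning):
            compute_dyad_density(fs)


class TestNormalization:
    def test_constant_track_becomes_one(self, layout):
        data = {"chrI": np.full(1000, 5.0), "chrII": np.full(2000, 0.5)}
        track = OccupancyTrack(layout, data, frozenset({"raw_coverage"}))
        norm = normalize_per_chromosome(track)
        for name in layout.names:
            assert np.allclose(norm.data[name], 1.0)

    def test_per_chromosome_mean_is_one(self, layout, rng):
        fs = random_fragments(layout, rng, n=400)
        norm = normalize_per_chromosome(compute_coverage(fs))
        for mean in norm.chromosome_means().values():
            assert abs(mean - 1.0) < 1e-9

    def test_idempotent(self, layout, rng):
        fs = random_fragments(layout, rng, n=400)
        once = normalize_per_chromosome(compute_coverage(fs))
        twice = normalize_per_chromosome(once)
        for name in layout.names:
            assert np.allclose(once.data[name], twice.data[name], atol=1e-12)

    def test_zero_signal_chromosome_left_at_zero(self, layout):
        data = {"chrI": np.ones(1000), "chrII": np.zeros(2000)}
        track = OccupancyTrack(layout, data, frozenset({"raw_coverage"}))
        with pytest.warns(UserWarning):
            norm = normalize_per_chromosome(track)
        assert norm.data["chrII"].sum() == 0.0


class TestMovingAverage:
    def test_constant_unchanged(self):
        assert np.allclose(moving_average(np.full(50, 3.0), 31), 3.0)

    def test_unit_impulse(self):
        x = np.zeros(101)
        x[50] = 1.0
        sm = moving_average(x, 31)
        assert np.allclose(sm[35:66], 1 / 31)
        assert sm[34] == 0 and sm[66] == 0

    def test_matches_brute_force_with_truncated_edges(self, rng):
        x = rng.random(200)
        span = 7
        sm = moving_average(x, span)
        for i in range(200):
            lo, hi = max(0, i - 3), min(200, i + 4)
            assert sm[i] == pytest.approx(x[lo:hi].mean())

    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(10), 4)

    def test_interior_mass_preserved(self, layout, rng):
        x = np.zeros(500)
        x[100:400] = rng.random(300)  # support away from edges
        assert moving_average(x, 31).sum() == pytest.approx(x.sum())


class TestMergeCorrectMaskDifference:
    def _norm(self, layout, rng, n=300):
        return normalize_per_chromosome(
            compute_coverage(random_fragments(layout, rng, n=n)))

    def test_merge_mean_and_permutation_invariance(self, layout, rng):
        a, b, c = (self._norm(layout, rng) for _ in range(3))
        m1 = merge_replicates([a, b, c])
        m2 = merge_replicates([c, a, b])
        for name in layout.names:
            assert np.allclose(
                m1.data[name], (a.data[name] + b.data[name] + c.data[name]) / 3)
            assert np.allclose(m1.data[name], m2.data[name], atol=1e-12)

    def test_merge_single_is_identity(self, layout, rng):
        a = self._norm(layout, rng)
        m = merge_replicates([a])
        for name in layout.names:
            assert np.array_equal(m.data[name], a.data[name])

    def test_merge_requires_normalized(self, layout, rng):
        raw = compute_coverage(random_fragments(layout, rng))
        with pytest.raises(ValueError):
            merge_replicates([raw])

    def test_background_self_correction_is_zero(self, layout, rng):
        a = self._norm(layout, rng)
        corr = correct_background(a, a)
        for name in layout.names:
            assert np.array_equal(corr.data[name], np.zeros_like(corr.data[name]))

    def test_background_negative_values_kept(self, layout, rng):
        tagged, untagged = self._norm(layout, rng), self._norm(layout, rng)
        corr = correct_background(tagged, untagged)
        assert any((corr.data[n] < 0).any() for n in layout.names)

    def test_mask_zeroes_interval_only(self, layout):
        data = {"chrI": np.ones(1000), "chrII": np.ones(2000)}
        track = OccupancyTrack(layout, data, frozenset({"normalized"}))
        masks = FeatureTable(layout, [Feature("t1", "chrI", 100, 350, ".",
                                              "tdna_flank")])
        masked = mask_intervals(track, masks)
        assert masked.data["chrI"].sum() == 1000 - 250
        assert masked.data["chrI"][99] == 1.0 and masked.data["chrI"][100] == 0.0
        assert np.array_equal(masked.data["chrII"], data["chrII"])

    def test_empty_mask_is_identity(self, layout):
        data = {"chrI": np.ones(1000), "chrII": np.ones(2000)}
        track = OccupancyTrack(layout, data, frozenset({"normalized"}))
        masked = mask_intervals(track, FeatureTable(layout, []))
        for name in layout.names:
            assert np.array_equal(masked.data[name], data[name])

    def test_difference_antisymmetry_and_chain(self, layout, rng):
        a, b, c = (self._norm(layout, rng) for _ in range(3))
        ab, ba = difference_track(a, b), difference_track(b, a)
        ac = difference_track(a, c)
        bc = difference_track(b, c)
        for name in layout.names:
            assert np.allclose(ab.data[name], -ba.data[name])
            assert np.allclose(ab.data[name] + bc.data[name], ac.data[name],
                               atol=1e-12)
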