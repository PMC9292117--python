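import numpy as np
import pandas as pd
import pytest

from ndrchip.io import Feature, FeatureTable
from ndrchip.quantify import (assign_peaks_to_genes, decile_bins,
                              default_pseudocount, fold_change_ranking,
                              half_bins, log2_table, occupancy_table,
                              quartile_sets, window_occupancy)
from ndrchip.tracks import OccupancyTrack


def make_track(layout, data):
    return OccupancyTrack(layout, data, frozenset({"normalized"}))


class TestWindowOccupancy:
    def test_constant_track(self, layout):
        t = make_track(layout, {"chrI": np.full(1000, 2.0),
                                "chrII": np.zeros(2000)})
        assert window_occupancy(t, "chrI", 100, 300) == 2.0

    def test_simple_mean(self, layout):
        values = np.zeros(1000)
        values[2:4] = 3.0
        t = make_track(layout, {"chrI": values, "chrII": np.zeros(2000)})
        assert window_occupancy(t, "chrI", 0, 4) == 1.5

    def test_matches_brute_force_on_random_windows(self, layout, rng):
        t = make_track(layout, {"chrI": rng.random(1000),
                                "chrII": rng.random(2000)})
        for _ in range(100):
            chrom = ("chrI", "chrII")[rng.integers(2)]
            length = t.layout.length(chrom)
            s = int(rng.integers(0, length - 10))
            e = int(rng.integers(s + 1, min(s + 200, length)))
            brute = sum(t.data[chrom][b] for b in range(s, e)) / (e - s)
            assert window_occupancy(t, chrom, s, e) == pytest.approx(brute)

    def test_truncated_at_chromosome_end(self, layout):
        t = make_track(layout, {"chrI": np.arange(1000.0),
                                "chrII": np.zeros(2000)})
        assert window_occupancy(t, "chrI", 990, 1100) == np.mean(
            np.arange(990.0, 1000.0))

    def test_zero_length_window(self, layout):
        t = make_track(layout, {"chrI": np.ones(1000), "chrII": np.ones(2000)})
        with pytest.raises(ValueError):
            window_occupancy(t, "chrI", 5, 5)


class TestLog2AndRanking:
    def _table(self):
        return pd.DataFrame({"mut": [1.0, 2.0, 0.5, 4.0],
                             "wt": [2.0, 2.0, 2.0, 2.0]},
                            index=["a", "b", "c", "d"])

    def test_log2_with_pseudocount(self):
        t = pd.DataFrame({"x": [3.0]}, index=["a"])
        out = log2_table(t, ["x"], pseudocount=1.0)
        assert out.loc["a", "log2_x"] == 2.0

    def test_log2_preserves_ranking(self, rng):
        t = pd.DataFrame({"x": rng.random(50) * 10},
                         index=[f"f{i}" for i in range(50)])
        out = log2_table(t, ["x"])
        assert (out["x"].rank() == out["log2_x"].rank()).all()

    def test_log2_rejects_negative(self):
        t = pd.DataFrame({"x": [-0.5]}, index=["a"])
        with pytest.raises(ValueError):
            log2_table(t, ["x"], pseudocount=1.0)

    def test_default_pseudocount_is_half_min_positive(self):
        t = pd.DataFrame({"x": [0.0, 0.8, 2.0]}, index=list("abc"))
        assert default_pseudocount(t, ["x"]) == 0.4

    def test_halved_feature_ranks_first(self):
        ranked = fold_change_ranking(self._table(), "mut", "wt")
        assert list(ranked.index)[0] == "c" and list(ranked.index)[-1] == "d"

    def test_equal_samples_rank_by_id(self):
        t = pd.DataFrame({"mut": [1.0, 1.0], "wt": [1.0, 1.0]},
                         index=["z", "a"])
        ranked = fold_change_ranking(t, "mut", "wt")
        assert list(ranked.index) == ["a", "z"]

    def test_order_matches_independent_sort(self, rng):
        t = pd.DataFrame({"mut": rng.random(80), "wt": rng.random(80) + 0.1},
                         index=[f"f{i:02d}" for i in range(80)])
        pc = default_pseudocount(t, ["mut", "wt"])
        ranked = fold_change_ranking(t, "mut", "wt", pseudocount=pc)
        oracle = sorted(t.index,
                        key=lambda i: ((t.at[i, "mut"] + pc) / (t.at[i, "wt"] + pc), i))
        assert list(ranked.index) == oracle

    def test_scale_invariance(self, rng):
        t = pd.DataFrame({"mut": rng.random(40) + 0.2,
                          "wt": rng.random(40) + 0.2},
                         index=[f"f{i:02d}" for i in range(40)])
        r1 = fold_change_ranking(t, "mut", "wt", pseudocount=1e-9)
        r2 = fold_change_ranking(t * 7.0, "mut", "wt", pseudocount=1e-9)
        assert list(r1.index) == list(r2.index)

    def test_logged_and_unlogged_ranking_agree(self, rng):
        # shared pseudocount makes ratio ranking order-equivalent in log space
        t = pd.DataFrame({"mut": rng.random(40), "wt": rng.random(40)},
                         index=[f"f{i:02d}" for i in range(40)])
        pc = default_pseudocount(t, ["mut", "wt"])
        ranked = fold_change_ranking(t, "mut", "wt", pseudocount=pc)
        logged = np.log2(t["mut"] + pc) - np.log2(t["wt"] + pc)
        oracle = sorted(t.index, key=lambda i: (logged[i], i))
        assert list(ranked.index) == oracle


class TestPartitions:
    @pytest.mark.parametrize("n,expected", [(117, (30, 57, 30)), (8, (2, 4, 2)),
                                            (10, (3, 4, 3)), (4, (1, 2, 1))])
    def test_quartile_set_sizes(self, n, expected):
        ids = [f"f{i:03d}" for i in range(n)]
        sizes = quartile_sets(ids).sizes()
        assert (sizes["Set_1"], sizes["Set_2"], sizes["Set_3"]) == expected

    def test_quartile_sets_keep_rank_order(self):
        ids = [f"f{i:03d}" for i in range(12)]
        part = quartile_sets(ids)
        assert part.members("Set_1") == ids[:3]
        assert part.members("Set_3") == ids[-3:]

    def test_quartile_too_small(self):
        with pytest.raises(ValueError):
            quartile_sets(["a", "b", "c"])

    @pytest.mark.parametrize("n,sizes", [(100, [10] * 10),
                                         (103, [11, 11, 11] + [10] * 7)])
    def test_decile_sizes(self, n, sizes):
        ids = [f"f{i:03d}" for i in range(n)]
        part = decile_bins(ids)
        assert [part.sizes()[f"Decile_{k}"] for k in range(1, 11)] == sizes

    def test_decile_partition_is_exact(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            ids = [f"f{i:03d}" for i in range(n)]
            part = decile_bins(ids)
            members = [m for label in part.order for m in part.members(label)]
            assert sorted(members) == sorted(ids) and len(set(members)) == n

    @pytest.mark.parametrize("n,high,low", [(4, 2, 2), (83, 42, 41)])
    def test_half_bins(self, n, high, low):
        ids = [f"f{i:03d}" for i in range(n)]
        part = half_bins(ids)
        assert part.sizes() == {"High": high, "Low": low}
        assert set(part.members("High")) | set(part.members("Low")) == set(ids)

    def test_more_bins_than_items(self):
        with pytest.raises(ValueError):
            decile_bins(["a"], k=10)


class TestPeakAssignment:
    def _tables(self, layout, summit_pos, tss_pos):
        summits = FeatureTable(layout, [
            Feature(f"s{i}", "chrI", p, p + 1, ".", "tbp_summit")
            for i, p in enumerate(summit_pos)])
        tss = FeatureTable(layout, [
            Feature(f"g{i}", "chrI", p, p + 1, "+", "tss")
            for i, p in enumerate(tss_pos)])
        return summits, tss

    def test_single_summit_serves_all(self, layout):
        summits, tss = self._tables(layout, [100], [90, 500])
        out = assign_peaks_to_genes(summits, tss, max_distance=None)
        assert out.loc["g0", "summit"] == "s0" and out.loc["g0", "distance"] == 10
        assert out.loc["g1", "distance"] == 400

    def test_equidistant_tie_goes_left(self, layout):
        summits, tss = self._tables(layout, [90, 110], [100])
        out = assign_peaks_to_genes(summits, tss)
        assert out.loc["g0", "summit"] == "s0"

    def test_distance_cutoff_reported(self, layout):
        summits, tss = self._tables(layout, [100], [900])
        out = assign_peaks_to_genes(summits, tss, max_distance=500)
        assert not out.loc["g0", "assigned"]

    def test_matches_exhaustive_oracle(self, layout, rng):
        for _ in range(100):
            s_pos = sorted(set(rng.integers(0, 999, size=6).tolist()))
            t_pos = rng.integers(0, 999, size=4).tolist()
            summits, tss = self._tables(layout, s_pos, t_pos)
            out = assign_peaks_to_genes(summits, tss, max_distance=None)
            for gi, tp in enumerate(t_pos):
                best = min(((abs(sp - tp), sp, f"s{si}")
                            for si, sp in enumerate(s_pos)))
                assert out.loc[f"g{gi}", "summit"] == best[2]
                assert out.loc[f"g{gi}", "distance"] == best[0]


class TestOccupancyTable:
    def test_window_modes_and_attributes(self, layout, rng):
        track = make_track(layout, {"chrI": rng.random(1000),
                                    "chrII": rng.random(2000)})
        feats = FeatureTable(layout, [
            Feature("pk", "chrI", 100, 301, "+", "gcn4_peak_5prime",
                    {"fimo_score": 12.0})])
        by_interval = occupancy_table({"s": track}, feats, flank=None)
        assert by_interval.loc["pk", "s"] == pytest.approx(
            track.data["chrI"][100:301].mean())
        assert by_interval.loc["pk", "fimo_score"] == 12.0
        by_flank = occupancy_table({"s": track}, feats, flank=50)
        assert by_flank.loc["pk", "s"] == pytest.approx(
            track.data["chrI"][150:251].mean())

    def test_rle_round_trip_leaves_windows_invariant(self, layout, rng, tmp_path):
        from ndrchip.io import read_track, write_track
        values = np.repeat(rng.integers(0, 5, size=100), 10).astype(float)
        track = make_track(layout, {"chrI": values, "chrII": np.ones(2000)})
        write_track(track, tmp_path / "t.bedGraph")
        back = read_track(tmp_path / "t.bedGraph", layout)
        for _ in range(20):
            s = int(rng.integers(0, 900))
            e = s + int(rng.integers(1, 100))
            assert window_occupancy(back, "chrI", s, e) == \
                window_occupancy(track, "chrI", s, e)
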