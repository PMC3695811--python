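import math

import numpy as np
import pytest

from senscall.calibration import CalibrationTable
from senscall.errors import ContractViolation, ParameterError
from senscall.intervals_io import (
    DepthProfile,
    GenomicInterval,
    TargetSet,
    merge_intervals,
    tile_targets,
)
from senscall.scoring import (
    TILE_DIFFICULT,
    TILE_EASY,
    TILE_INTERMEDIATE,
    aggregate_regions,
    classify_tiles,
    covered_target_sets,
    flag_capture_failures,
    per_base_sensitivity,
    required_mean_depth,
    tile_gc,
    tile_sharing,
    total_sensitivity,
)

from conftest import random_intervals


def make_table(rng=None, max_depth=100):
    if rng is None:
        het = np.minimum(np.arange(max_depth + 1) / 15.0, 1.0)
        hom = np.minimum(np.arange(max_depth + 1) / 4.0, 1.0)
    else:
        het = np.sort(rng.random(max_depth + 1))
        hom = np.sort(rng.random(max_depth + 1))
    return CalibrationTable({"het": het, "hom": hom})


@pytest.fixture
def target():
    return TargetSet([GenomicInterval("chr1", 0, 200), GenomicInterval("chr1", 300, 400)])


class TestPerBaseSensitivity:
    def test_zero_depth_gives_zero(self, target):
        prof = DepthProfile(target, np.zeros(300, dtype=int))
        track = per_base_sensitivity(prof, make_table())
        assert track.values["het"].sum() == 0.0
        assert track.values["hom"].sum() == 0.0

    def test_constant_depth_constant_track(self, target):
        table = make_table()
        prof = DepthProfile(target, np.full(300, 8))
        track = per_base_sensitivity(prof, table)
        assert np.all(track.values["het"] == table.sens["het"][8])
        assert np.all(track.values["hom"] == table.sens["hom"][8])

    def test_depth_above_table_clamped(self, target):
        table = make_table(max_depth=50)
        prof = DepthProfile(target, np.full(300, 500))
        track = per_base_sensitivity(prof, table)
        assert np.all(track.values["het"] == table.sens["het"][50])

    def test_random_profile_matches_naive_lookup(self, rng, target):
        table = make_table(rng)
        depths = rng.integers(0, 120, size=300)
        prof = DepthProfile(target, depths)
        track = per_base_sensitivity(prof, table)
        for g in ("het", "hom"):
            expected = np.array(
                [table.sens[g][min(int(d), 100)] for d in depths]
            )
            expected[depths == 0] = 0.0
            assert np.array_equal(track.values[g], expected)

    def test_undefined_row_at_occurring_depth_errors(self, target):
        sens = {"het": np.array([0.0, np.nan, 0.9]),
                "hom": np.array([0.0, 0.5, 0.9])}
        table = CalibrationTable(sens)
        prof = DepthProfile(target, np.full(300, 1))
        with pytest.raises(ParameterError, match="1"):
            per_base_sensitivity(prof, table)


class TestAggregateRegions:
    def test_two_equal_regions_weighted_mean(self):
        target = TargetSet([GenomicInterval("chr1", 0, 20)])
        table = make_table()
        prof = DepthProfile(target, np.r_[np.full(10, 12), np.full(10, 15)])
        track = per_base_sensitivity(prof, table)
        regions = [("a", GenomicInterval("chr1", 0, 10)),
                   ("b", GenomicInterval("chr1", 10, 20))]
        reports = aggregate_regions(track, regions)
        whole = aggregate_regions(track, [("all", GenomicInterval("chr1", 0, 20))])[0]
        combined = 0.5 * reports[0].mean["het"] + 0.5 * reports[1].mean["het"]
        assert combined == pytest.approx(whole.mean["het"], abs=1e-15)
        assert reports[0].mean["het"] == pytest.approx(12 / 15)
        assert reports[1].mean["het"] == pytest.approx(1.0)

    def test_single_base_region(self, target):
        prof = DepthProfile(
            target, np.arange(300) % 20
        )
        track = per_base_sensitivity(prof, make_table())
        (rep,) = aggregate_regions(track, [("x", GenomicInterval("chr1", 7, 8))])
        assert rep.length == 1
        assert rep.mean["het"] == rep.minimum["het"]

    def test_random_partition_conservation(self, rng):
        target = merge_intervals(random_intervals(rng, n=10, span=2000,
                                                  chroms=("chr1",)))
        table = make_table(rng)
        prof = DepthProfile(target, rng.integers(0, 80, size=target.total_length))
        track = per_base_sensitivity(prof, table)
        # partition: the target intervals themselves
        regions = [(f"r{i}", iv) for i, iv in enumerate(target)]
        reports = aggregate_regions(track, regions)
        total_len = sum(r.length for r in reports)
        assert total_len == target.total_length
        for g in ("het", "hom"):
            recombined = sum(r.mean[g] * r.length for r in reports) / total_len
            assert recombined == pytest.approx(
                float(track.values[g].mean()), abs=1e-12
            )

    def test_zero_overlap_region_flagged(self, target):
        prof = DepthProfile(target, np.full(300, 5))
        track = per_base_sensitivity(prof, make_table())
        (rep,) = aggregate_regions(track, [("gap", GenomicInterval("chr1", 250, 260))])
        assert not rep.defined
        assert math.isnan(rep.mean["het"])

    def test_missed_fraction(self, target):
        prof = DepthProfile(target, np.full(300, 8))
        table = make_table()
        track = per_base_sensitivity(prof, table)
        (rep,) = aggregate_regions(track, [("all", GenomicInterval("chr1", 0, 400))])
        assert rep.missed_fraction["het"] == pytest.approx(1 - table.sens["het"][8])


class TestTotalSensitivity:
    def test_uniform_depth(self, target):
        table = make_table()
        prof = DepthProfile(target, np.full(300, 6))
        totals = total_sensitivity(prof, table)
        assert totals["het"] == pytest.approx(table.sens["het"][6])

    def test_half_ones_half_zeros(self):
        target = TargetSet([GenomicInterval("chr1", 0, 100)])
        sens = np.zeros(101)
        sens[20] = 1.0
        table = CalibrationTable({"het": sens, "hom": sens})
        depths = np.r_[np.full(50, 20), np.zeros(50, dtype=int)]
        totals = total_sensitivity(DepthProfile(target, depths), table)
        assert totals["het"] == pytest.approx(0.5)

    def test_equals_track_mean(self, rng, target):
        table = make_table(rng)
        prof = DepthProfile(target, rng.integers(0, 150, size=300))
        track = per_base_sensitivity(prof, table)
        totals = total_sensitivity(prof, table)
        for g in ("het", "hom"):
            assert totals[g] == pytest.approx(float(track.values[g].mean()),
                                              abs=1e-12)

    def test_monotone_under_depth_increase(self, rng, target):
        table = make_table()  # monotone table
        d1 = rng.integers(0, 60, size=300)
        d2 = d1 + rng.integers(0, 10, size=300)
        t1 = total_sensitivity(DepthProfile(target, d1), table)
        t2 = total_sensitivity(DepthProfile(target, d2), table)
        assert t2["het"] >= t1["het"]
        assert t2["hom"] >= t1["hom"]


class TestRequiredMeanDepth:
    def test_linear_interpolation_example(self):
        req = required_mean_depth([(10, 0.8), (20, 0.9)], levels=[0.85])
        assert req[0.85] == pytest.approx(15.0)

    def test_unattained_level(self):
        req = required_mean_depth([(10, 0.8), (20, 0.9)], levels=[0.95])
        assert req[0.95] is None

    def test_monotone_in_level(self, rng):
        depths = np.arange(2, 40, 2)
        sens = 1 - np.exp(-depths / 10.0) + rng.normal(0, 0.01, size=len(depths))
        pts = list(zip(depths.tolist(), sens.tolist()))
        req = required_mean_depth(pts, levels=[0.5, 0.7, 0.9])
        vals = [req[0.5], req[0.7], req[0.9]]
        assert all(v is not None for v in vals)
        assert vals[0] <= vals[1] <= vals[2]

    def test_noisy_series_brackets_true_crossing(self, rng):
        # logistic-like true curve; noise small relative to spacing
        depths = np.arange(1, 41)
        true = depths / (depths + 5.0)
        noisy = np.clip(true + rng.normal(0, 0.005, size=len(depths)), 0, 1)
        pts = list(zip(depths.tolist(), noisy.tolist()))
        level = 0.8
        true_crossing = 20.0  # d/(d+5) = 0.8 at d = 20
        req = required_mean_depth(pts, levels=[level])[level]
        lo = max(d for d, t in zip(depths, true) if t < level)
        hi = min(d for d, t in zip(depths, true) if t >= level)
        assert lo - 1 <= req <= hi + 1
        assert abs(req - true_crossing) <= 2.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            required_mean_depth([(10, 0.5)])


class TestClassifyTiles:
    def _profiles(self, full_depths, p01_depths):
        n = len(full_depths)
        target = TargetSet([GenomicInterval("chr1", 0, n)])
        tiles = tile_targets(target)
        full = DepthProfile(target, np.asarray(full_depths))
        p01 = DepthProfile(target, np.asarray(p01_depths))
        return full, p01, tiles

    def test_easy_tile_90pct_rule_at_p01(self):
        full = [50] * 100
        p01 = [12] * 95 + [2] * 5  # 95% well-covered at p = 0.1
        fullp, p01p, tiles = self._profiles(full, p01)
        (tc,) = classify_tiles(fullp, p01p, tiles)
        assert tc.label == TILE_EASY
        assert tc.well_covered

    def test_difficult_tile_max_depth_nine(self):
        fullp, p01p, tiles = self._profiles([9] * 100, [1] * 100)
        (tc,) = classify_tiles(fullp, p01p, tiles)
        assert tc.label == TILE_DIFFICULT
        assert not tc.well_covered

    def test_intermediate_tile(self):
        full = [50] * 50 + [5] * 50  # 50% well-covered: not difficult
        p01 = [5] * 100  # not easy at p = 0.1
        fullp, p01p, tiles = self._profiles(full, p01)
        (tc,) = classify_tiles(fullp, p01p, tiles)
        assert tc.label == TILE_INTERMEDIATE

    def test_89pct_at_p01_is_not_easy(self):
        full = [50] * 100
        p01 = [12] * 89 + [2] * 11
        fullp, p01p, tiles = self._profiles(full, p01)
        (tc,) = classify_tiles(fullp, p01p, tiles)
        assert tc.label == TILE_INTERMEDIATE

    def test_small_tile_ceiling_rule(self):
        # 5-base remainder tile: 90% of 5 = 4.5 -> all 5 bases required
        target = TargetSet([GenomicInterval("chr1", 0, 105)])
        tiles = tile_targets(target)
        depths = np.full(105, 50)
        depths[104] = 2  # 4/5 well-covered in the small tile
        full = DepthProfile(target, depths)
        out = classify_tiles(full, full, tiles)
        assert out[0].label == TILE_EASY
        assert out[1].label == TILE_INTERMEDIATE
        assert not out[1].well_covered

    def test_difficult_and_easy_mutually_exclusive(self, rng):
        target = TargetSet([GenomicInterval("chr1", 0, 1000)])
        tiles = tile_targets(target)
        full = DepthProfile(target, rng.integers(0, 30, size=1000))
        p01 = DepthProfile(target, rng.integers(0, 15, size=1000))
        for tc in classify_tiles(full, p01, tiles):
            assert tc.label in (TILE_DIFFICULT, TILE_EASY, TILE_INTERMEDIATE)
            if tc.label == TILE_DIFFICULT:
                assert not tc.well_covered

    def test_gc_annotation(self):
        target = TargetSet([GenomicInterval("chr1", 0, 4)])
        tiles = tile_targets(target)
        full = DepthProfile(target, np.full(4, 20))
        reference = {"chr1": "GGCC"}
        (tc,) = classify_tiles(full, full, tiles, reference)
        assert tc.gc == 1.0


class TestTileGc:
    def _tile(self, length):
        iv = GenomicInterval("chr1", 0, length)
        from senscall.intervals_io import Tile

        return Tile(iv, iv, 0)

    def test_all_gc(self):
        assert tile_gc(self._tile(4), {"chr1": "GGCC"}) == 1.0

    def test_all_at(self):
        assert tile_gc(self._tile(4), {"chr1": "ATAT"}) == 0.0

    def test_ambiguous_excluded(self):
        assert tile_gc(self._tile(4), {"chr1": "GANT"}) == pytest.approx(1 / 3)

    def test_all_ambiguous_nan(self):
        assert math.isnan(tile_gc(self._tile(3), {"chr1": "NNN"}))


def _tc(chrom, start, end, label):
    from senscall.intervals_io import Tile
    from senscall.scoring import TileClassification

    iv = GenomicInterval(chrom, start, end)
    return TileClassification(Tile(iv, iv, 0), label, label == TILE_EASY)


class TestTileSharing:
    def test_identical_classifications(self):
        tcs = [_tc("chr1", i * 100, (i + 1) * 100, TILE_DIFFICULT) for i in range(5)]
        matrix, mean, sd = tile_sharing({"a": tcs, "b": list(tcs)}, TILE_DIFFICULT)
        assert set(matrix.values()) == {1.0}
        assert mean == 1.0

    def test_disjoint_sets(self):
        a = [_tc("chr1", 0, 100, TILE_DIFFICULT)]
        b = [_tc("chr1", 100, 200, TILE_DIFFICULT)]
        matrix, mean, _ = tile_sharing({"a": a, "b": b}, TILE_DIFFICULT)
        assert mean == 0.0

    def test_random_sets_match_brute_force(self, rng):
        samples = {}
        sets = {}
        for s in "abcd":
            keys = set(int(k) for k in rng.choice(50, size=20, replace=False))
            sets[s] = keys
            samples[s] = [
                _tc("chr1", k * 10, k * 10 + 10,
                    TILE_DIFFICULT if k in keys else TILE_INTERMEDIATE)
                for k in range(50)
            ]
        matrix, _, _ = tile_sharing(samples, TILE_DIFFICULT)
        for (a, b), frac in matrix.items():
            assert frac == pytest.approx(len(sets[a] & sets[b]) / len(sets[a]))

    def test_empty_class_pair_skipped(self):
        a = [_tc("chr1", 0, 100, TILE_INTERMEDIATE)]
        b = [_tc("chr1", 0, 100, TILE_DIFFICULT)]
        matrix, _, _ = tile_sharing({"a": a, "b": b}, TILE_DIFFICULT)
        assert ("a", "b") not in matrix
        assert matrix[("b", "a")] == 0.0

    def test_needs_two_samples(self):
        with pytest.raises(ParameterError):
            tile_sharing({"a": []}, TILE_DIFFICULT)


class TestCoveredTargetSets:
    def test_single_method_union(self):
        per_method, inter = covered_target_sets(
            {"m1": {"s1": [("chr1", 0, 100), ("chr1", 100, 200)]}}
        )
        assert per_method["m1"] == {("chr1", 0, 100), ("chr1", 100, 200)}
        assert inter == per_method["m1"]

    def test_intersection_of_methods(self):
        per_method, inter = covered_target_sets(
            {
                "m1": {"s1": [("chr1", 0, 100)], "s2": [("chr1", 100, 200)]},
                "m2": {"s3": [("chr1", 100, 200), ("chr1", 200, 300)]},
            }
        )
        assert inter == {("chr1", 100, 200)}

    def test_random_matches_brute_force(self, rng):
        cover = {}
        for m in ("m1", "m2", "m3"):
            cover[m] = {
                f"{m}_s{i}": [("chr1", int(k) * 10, int(k) * 10 + 10)
                              for k in rng.choice(30, size=10, replace=False)]
                for i in range(3)
            }
        per_method, inter = covered_target_sets(cover)
        for m, samples in cover.items():
            expected = set()
            for tiles in samples.values():
                expected |= set(tiles)
            assert per_method[m] == expected
        assert inter == per_method["m1"] & per_method["m2"] & per_method["m3"]

    def test_empty_method_rejected(self):
        with pytest.raises(ParameterError):
            covered_target_sets({"m1": {}})


class TestFlagCaptureFailures:
    def test_outlier_flagged(self):
        flagged = flag_capture_failures({"a": 100, "b": 98, "c": 99, "d": 40})
        assert flagged == ["d"]

    def test_identical_counts_none_flagged(self):
        assert flag_capture_failures({"a": 50, "b": 50, "c": 50}) == []

    def test_infinite_k_none_flagged(self):
        counts = {"a": 100, "b": 98, "c": 40}
        assert flag_capture_failures(counts, k_mad=math.inf) == []

    def test_needs_three_samples(self):
        with pytest.raises(ParameterError):
            flag_capture_failures({"a": 1, "b": 2})
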