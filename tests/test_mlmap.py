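import numpy as np
import pytest

from emmap import (
    ApEnParams,
    MapCollection,
    MultilevelMap,
    VelocitySeries,
    approximate_entropy,
    average_maps,
    build_map,
    n_levels,
    normalize_level,
    sd,
    segment_bounds,
)
from emmap.mlmap import DegenerateRangeError, StructureError, cells_at_level


class TestSegmentBounds:
    @pytest.mark.parametrize(
        "level, index, expected",
        [
            (1, 3, (128, 192)),
            (2, 2, (128, 256)),
            (5, 1, (0, 1024)),
            (1, 1, (0, 64)),
            (4, 2, (512, 1024)),
        ],
    )
    def test_default_geometry(self, level, index, expected):
        assert segment_bounds(level, index) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(StructureError):
            segment_bounds(6, 1)
        with pytest.raises(StructureError):
            segment_bounds(2, 9)
        with pytest.raises(StructureError):
            segment_bounds(0, 1)

    def test_level_count_and_cells(self):
        assert n_levels(1024, 64) == 5
        assert [cells_at_level(l) for l in range(1, 6)] == [16, 8, 4, 2, 1]
        with pytest.raises(StructureError):
            n_levels(1024, 60)

    def test_children_tile_parent_exactly(self):
        for level in range(2, 6):
            for index in range(1, cells_at_level(level) + 1):
                start, end = segment_bounds(level, index)
                left = segment_bounds(level - 1, 2 * index - 1)
                right = segment_bounds(level - 1, 2 * index)
                assert left[0] == start
                assert left[1] == right[0]
                assert right[1] == end


class TestBuildMap:
    def test_constant_series_all_entropy_cells_zero(self):
        series = VelocitySeries(samples=np.full(1024, 2.0))
        for measure in ("ApEn", "FuzEn"):
            mm = build_map(series, measure)
            for level in mm.levels:
                np.testing.assert_array_equal(level, 0.0)

    def test_top_cell_equals_whole_series_measure(self, rng):
        u = rng.normal(size=1024)
        series = VelocitySeries(samples=u)
        mm = build_map(series, "ApEn")
        expected = approximate_entropy(u, 0.2 * sd(u), m=2)
        assert mm.cell(5, 1) == pytest.approx(expected, abs=1e-14)

    def test_cells_use_exact_segment_windows(self, rng):
        u = rng.normal(size=1024)
        series = VelocitySeries(samples=u)
        mm = build_map(series, "ApEn")
        r = 0.2 * sd(u)
        assert mm.cell(1, 3) == pytest.approx(approximate_entropy(u[128:192], r), abs=1e-14)
        assert mm.cell(2, 2) == pytest.approx(approximate_entropy(u[128:256], r), abs=1e-14)

    def test_deterministic(self, rng):
        series = VelocitySeries(samples=rng.normal(size=1024))
        m1 = build_map(series, "FuzEn")
        m2 = build_map(series, "FuzEn")
        for a, b in zip(m1.levels, m2.levels):
            np.testing.assert_array_equal(a, b)

    def test_segment_scope_tolerance(self, rng):
        u = rng.normal(size=1024)
        series = VelocitySeries(samples=u)
        mm = build_map(series, "ApEn", ApEnParams(r_scope="segment"))
        seg = u[0:64]
        assert mm.cell(1, 1) == pytest.approx(
            approximate_entropy(seg, 0.2 * seg.std(), m=2), abs=1e-14
        )

    def test_saccade_cells_are_entropy_minima(self, demo_collection):
        """Generator property: the saccade window (cells (1,3), (1,4), (2,2))
        holds each entropy map's per-level minimum in >= 90% of series."""
        n = len(demo_collection.series_meta)
        for measure in ("ApEn", "FuzEn"):
            level1_hits = level2_hits = 0
            for mm in demo_collection.maps[measure]:
                level1_hits += int(np.nanargmin(mm.levels[0])) + 1 in (3, 4)
                level2_hits += int(np.nanargmin(mm.levels[1])) + 1 == 2
            assert level1_hits >= 0.9 * n, f"{measure} level-1 minima: {level1_hits}/{n}"
            assert level2_hits >= 0.9 * n, f"{measure} level-2 minima: {level2_hits}/{n}"


class TestAverageMaps:
    def _map_from(self, levels):
        return MultilevelMap("ApEn", 64, 1024, levels)

    def _levels(self, fill):
        return [np.full(cells_at_level(l), fill) for l in range(1, 6)]

    def test_identity_on_identical_maps(self):
        mm = self._map_from(self._levels(1.5))
        avg = average_maps([mm, self._map_from(self._levels(1.5))])
        for level in avg.levels:
            np.testing.assert_array_equal(level, 1.5)

    def test_missing_cell_uses_remaining_values(self):
        a = self._levels(2.0)
        a[0][3] = np.nan
        avg = average_maps([self._map_from(a), self._map_from(self._levels(4.0))])
        assert avg.levels[0][3] == 4.0
        assert avg.levels[0][0] == 3.0

    def test_cell_missing_only_if_missing_everywhere(self):
        a, b = self._levels(1.0), self._levels(2.0)
        a[2][1] = np.nan
        b[2][1] = np.nan
        avg = average_maps([self._map_from(a), self._map_from(b)])
        assert np.isnan(avg.levels[2][1])

    def test_structure_mismatch_rejected(self):
        other = MultilevelMap(
            "FuzEn", 64, 1024, [np.zeros(cells_at_level(l)) for l in range(1, 6)]
        )
        with pytest.raises(StructureError):
            average_maps([self._map_from(self._levels(0.0)), other])


class TestNormalization:
    def test_affine_to_unit_interval(self):
        np.testing.assert_allclose(normalize_level([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])

    def test_idempotent_on_attained_bounds(self, rng):
        values = np.concatenate([[0.0, 1.0], rng.uniform(size=20)])
        np.testing.assert_allclose(normalize_level(values), values, atol=1e-15)

    def test_invertible(self, rng):
        values = rng.normal(size=50) * 7 + 3
        scaled = normalize_level(values)
        recovered = scaled * (values.max() - values.min()) + values.min()
        np.testing.assert_allclose(recovered, values, atol=1e-12)

    def test_degenerate_range_rejected(self):
        with pytest.raises(DegenerateRangeError):
            normalize_level([3.0, 3.0, 3.0])

    def test_collection_normalized_values_in_unit_interval(self, demo_collection):
        for measure, maps in demo_collection.normalized.items():
            for mm in maps:
                for level in mm.levels:
                    finite = level[np.isfinite(level)]
                    assert (finite >= 0).all() and (finite <= 1).all()


class TestMapCollection:
    def test_dataframe_round_trip(self, demo_collection):
        df = demo_collection.to_dataframe()
        rebuilt = MapCollection.from_dataframe(df)
        assert rebuilt.nss == demo_collection.nss
        assert rebuilt.nemr == demo_collection.nemr
        for measure in demo_collection.measures:
            for original, copy in zip(
                demo_collection.maps[measure], rebuilt.maps[measure]
            ):
                for a, b in zip(original.levels, copy.levels):
                    np.testing.assert_allclose(b, a, atol=0, rtol=0)

    def test_average_reproduces_saccade_signature(self, demo_collection):
        for measure in ("ApEn", "FuzEn"):
            avg = demo_collection.average(measure)
            two_lowest = set(np.argsort(avg.levels[0])[:2] + 1)
            assert two_lowest == {3, 4}
            assert int(np.nanargmin(avg.levels[1])) + 1 == 2


def test_plot_map_writes_figure(tmp_path, demo_collection):
    out = tmp_path / "map.png"
    from emmap import plot_map

    plot_map(demo_collection.average("ApEn"), path=str(out))
    assert out.stat().st_size > 0
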