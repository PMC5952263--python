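"""Conformity metrics against analytic values and brute-force raster oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cordprop.conformity import (
    METRICS,
    aggregate,
    boxplot_stats,
    compare_structure_sets,
    conformity_index,
    dimension_differences,
    distance_between_centres,
    distance_to_conformity,
    interobserver_analysis,
)
from cordprop.image_io import Contour, StructureSet

from conftest import square


def raster_dtc_oracle(poly_a, poly_b, pitch=0.1):
    """Brute-force pixel oracle: mean distance from symmetric difference
    pixels to the nearest intersection pixel, by exhaustive search."""
    from shapely.geometry import Polygon
    import shapely

    ra, rb = Polygon(poly_a), Polygon(poly_b)
    minx = min(ra.bounds[0], rb.bounds[0]) - 2 * pitch
    miny = min(ra.bounds[1], rb.bounds[1]) - 2 * pitch
    maxx = max(ra.bounds[2], rb.bounds[2]) + 2 * pitch
    maxy = max(ra.bounds[3], rb.bounds[3]) + 2 * pitch
    xs = np.arange(minx + pitch / 2, maxx, pitch)
    ys = np.arange(miny + pitch / 2, maxy, pitch)
    gx, gy = np.meshgrid(xs, ys)
    in_a = shapely.intersects_xy(ra, gx.ravel(), gy.ravel()).reshape(gx.shape)
    in_b = shapely.intersects_xy(rb, gx.ravel(), gy.ravel()).reshape(gx.shape)
    inter = in_a & in_b
    sym = (in_a | in_b) & ~inter
    ix, iy = gx[inter], gy[inter]
    dists = []
    for px, py in zip(gx[sym], gy[sym]):
        dists.append(np.min(np.hypot(ix - px, iy - py)))
    return float(np.mean(dists))


class TestConformityIndex:
    def test_identical_is_one(self):
        s = square(10)
        assert conformity_index(s, s) == pytest.approx(1.0)

    def test_offset_squares_give_one_third(self):
        a = square(10)
        b = square(10, centre=(5, 0))
        assert conformity_index(a, b) == pytest.approx(1 / 3, abs=1e-12)

    def test_disjoint_is_zero(self):
        assert conformity_index(square(10), square(10, centre=(30, 0))) == 0.0

    def test_symmetry(self):
        a, b = square(10), square(8, centre=(3, 2))
        assert conformity_index(a, b) == pytest.approx(conformity_index(b, a))


class TestDistanceBetweenCentres:
    def test_identical_is_zero(self):
        s = square(10)
        assert distance_between_centres(s, s) == pytest.approx(0.0)

    def test_three_four_shift_gives_five(self):
        a = square(10)
        b = square(10, centre=(3, 4))
        assert distance_between_centres(a, b) == pytest.approx(5.0)

    def test_concentric_different_sizes_is_zero(self):
        assert distance_between_centres(square(10), square(6)) == pytest.approx(0.0)


class TestDimensionDifferences:
    def test_identical_is_zero(self):
        s = square(10)
        assert dimension_differences(s, s) == (0.0, 0.0)

    def test_wider_test_positive_lr(self):
        a = np.array([[-6, -5], [6, -5], [6, 5], [-6, 5]], dtype=float)  # 12 x 10
        b = np.array([[-5, -5], [5, -5], [5, 5], [-5, 5]], dtype=float)  # 10 x 10
        assert dimension_differences(a, b) == pytest.approx((2.0, 0.0))

    def test_rotated_rectangle_swaps_signs(self):
        rect = np.array([[-6, -4], [6, -4], [6, 4], [-6, 4]], dtype=float)  # 12 x 8
        rot = rect[:, ::-1].copy()  # 90-degree rotation: 8 x 12
        lr, ap = dimension_differences(rect, rot)
        assert (lr, ap) == pytest.approx((4.0, -4.0))

    def test_antisymmetry(self):
        a, b = square(12), square(9)
        lr_ab, ap_ab = dimension_differences(a, b)
        lr_ba, ap_ba = dimension_differences(b, a)
        assert lr_ab == pytest.approx(-lr_ba)
        assert ap_ab == pytest.approx(-ap_ba)


class TestDistanceToConformity:
    def test_identical_is_zero(self):
        s = square(10)
        assert distance_to_conformity(s, s) == 0.0

    def test_offset_squares_match_oracle(self):
        a, b = square(10), square(10, centre=(1, 0))
        got = distance_to_conformity(a, b)
        expect = raster_dtc_oracle(a, b)
        assert got == pytest.approx(expect, abs=0.02)

    def test_nested_squares_match_oracle(self):
        a, b = square(10), square(8)
        got = distance_to_conformity(a, b)
        expect = raster_dtc_oracle(a, b)
        assert got == pytest.approx(expect, abs=0.02)

    def test_scale_behaviour(self):
        """Scaling both polygons scales DTC (and DBC) but not CI."""
        a, b = square(10), square(10, centre=(2, 1))
        s = 2.0
        assert conformity_index(s * a, s * b) == pytest.approx(conformity_index(a, b))
        assert distance_between_centres(s * a, s * b) == pytest.approx(
            s * distance_between_centres(a, b)
        )
        assert distance_to_conformity(s * a, s * b) == pytest.approx(
            s * distance_to_conformity(a, b), rel=0.05
        )


class TestRasterPolygonAgreement:
    @given(
        side=st.floats(4.0, 20.0),
        dx=st.floats(-3.0, 3.0),
        dy=st.floats(-3.0, 3.0),
    )
    @settings(max_examples=20, deadline=None)
    def test_raster_and_clipping_areas_agree(self, side, dx, dy):
        """Rasterised intersection area matches shapely within 1%."""
        import shapely
        from shapely.geometry import Polygon

        a = Polygon(square(side))
        b = Polygon(square(side, centre=(dx, dy)))
        inter = a.intersection(b)
        pitch = 0.1
        # grid offset avoids pixel centres landing exactly on polygon edges
        xs = np.arange(-side, side, pitch) + pitch * 0.4371
        gx, gy = np.meshgrid(xs, xs)
        raster = shapely.intersects_xy(inter, gx.ravel(), gy.ravel()).sum() * pitch**2
        # discretisation error is bounded by half a pixel along the boundary
        bound = max(0.01 * inter.area, 0.5 * inter.length * pitch)
        assert abs(raster - inter.area) <= bound + 1e-9


def _ss(z_values, maker):
    return StructureSet(
        "s", [Contour(z, maker(z)) for z in z_values], frame="f"
    )


class TestCompareStructureSets:
    def test_self_comparison_is_perfect(self, circle_structure):
        result = compare_structure_sets(circle_structure, circle_structure)
        assert len(result) == len(circle_structure.contours)
        for r in result:
            assert r.ci == pytest.approx(1.0)
            assert r.dbc == pytest.approx(0.0, abs=1e-9)
            assert r.dtc == 0.0

    def test_missing_superior_slices_reported_unmatched(self):
        ref = _ss(np.arange(0, 30, 3.0), lambda z: square(10))
        test = _ss(np.arange(0, 24, 3.0), lambda z: square(10))
        result = compare_structure_sets(test, ref)
        assert len(result.records) == 8
        assert len(result.unmatched_reference) == 2
        assert not result.unmatched_test

    def test_no_matching_slices_raises(self):
        a = _ss([0.0, 3.0], lambda z: square(10))
        b = _ss([100.0, 103.0], lambda z: square(10))
        with pytest.raises(ValueError, match="no matched slices"):
            compare_structure_sets(a, b)

    def test_in_plane_translation_dbc(self):
        a = _ss([0.0, 3.0], lambda z: square(10))
        b = _ss([0.0, 3.0], lambda z: square(10, centre=(3, 4)))
        result = compare_structure_sets(a, b)
        for r in result:
            assert r.dbc == pytest.approx(5.0)


class TestAggregate:
    def test_hand_computed_summary(self):
        records = [
            type("R", (), dict(z=z, ci=c, dtc=0.0, dbc=0.0, lr_diff=0.0, ap_diff=0.0))()
            for z, c in zip((0, 3, 6), (0.7, 0.8, 0.9))
        ]
        summary = aggregate(records)
        assert summary["ci"].mean == pytest.approx(0.8)
        assert summary["ci"].median == pytest.approx(0.8)
        assert summary["ci"].sd == pytest.approx(0.1)
        assert summary["ci"].se_mean == pytest.approx(0.1 / np.sqrt(3))

    def test_single_record_uncertainties_unavailable(self):
        records = [
            type("R", (), dict(z=0, ci=0.5, dtc=0.1, dbc=0.2, lr_diff=0, ap_diff=0))()
        ]
        summary = aggregate(records)
        assert summary["ci"].sd is None
        assert summary["ci"].se_median is None

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(0)
        records = [
            type("R", (), dict(z=i, ci=v, dtc=0, dbc=0, lr_diff=0, ap_diff=0))()
            for i, v in enumerate(rng.random(40))
        ]
        s1 = aggregate(records, seed=7)
        s2 = aggregate(records, seed=7)
        assert s1["ci"].se_median == s2["ci"].se_median

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_boxplot_stats_fields(self):
        stats = boxplot_stats([1.0, 2.0, 3.0, 4.0])
        assert stats["min"] == 1.0 and stats["max"] == 4.0
        assert stats["median"] == pytest.approx(2.5)


class TestInterobserver:
    def _observers(self, n, jitter=0.0):
        out = []
        for i in range(n):
            out.append(
                _ss(np.arange(0, 12, 3.0), lambda z, i=i: square(10 + jitter * i))
            )
        return out

    def test_six_observers_fifteen_pairs(self):
        result = interobserver_analysis(self._observers(6))
        assert result.n_pairs == 15

    def test_four_observers_six_pairs(self):
        assert interobserver_analysis(self._observers(4)).n_pairs == 6

    def test_identical_observers_mean_ci_one(self):
        result = interobserver_analysis(self._observers(6))
        for per in result.per_observer:
            assert per["ci"] == pytest.approx(1.0)
        assert result.mean_of_pairs["ci"] == pytest.approx(1.0)

    def test_signed_metric_orientation_flips(self):
        obs = self._observers(3, jitter=1.0)  # observer i draws 10+i wide
        result = interobserver_analysis(obs)
        # observer 0 is narrower than the others: negative lr as test
        assert result.per_observer[0]["lr_diff"] < 0
        assert result.per_observer[2]["lr_diff"] > 0

    def test_fewer_than_two_observers_raises(self):
        with pytest.raises(ValueError):
            interobserver_analysis(self._observers(1))
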