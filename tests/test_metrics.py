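import numpy as np
import pytest

from gimotion.core import ContourSeries
from gimotion.metrics import (
    centroid_series,
    compare_paired,
    dgy_trace,
    dm_area,
    dm_gravity,
    dm_velocity,
    gastric_residual,
    wall_velocities,
)

DT = 0.656


def _circle_series(radii, n=100, center=(0.0, 0.0), rotate_per_frame=0.0):
    """Material-corresponded circle contours: frame t has radius radii[t]
    and is rigidly rotated by t * rotate_per_frame radians."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    frames = []
    for t, r in enumerate(radii):
        a = th + t * rotate_per_frame
        frames.append(np.column_stack([center[0] + r * np.cos(a),
                                       center[1] + r * np.sin(a)]))
    return ContourSeries(points=np.stack(frames), structure_label="duodenum",
                         frame_interval=DT)


class TestDmArea:
    def test_constant_series_is_zero(self):
        assert dm_area(np.full(40, 123.0)) == 0.0

    def test_alternating_areas_hand_computed(self):
        # 40 frames alternating 90, 110: sample SD by the direct formula
        areas = np.tile([90.0, 110.0], 20)
        s = np.sqrt(np.sum((areas - 100.0) ** 2) / 39)
        assert dm_area(areas) == pytest.approx(100 * s / 100.0)
        assert dm_area(areas) == pytest.approx(10.1, abs=0.1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(80, 120, 40)
        assert dm_area(areas * 7.3) == pytest.approx(dm_area(areas), rel=1e-12)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            dm_area(np.array([100.0]))


class TestDmGravity:
    def test_static_centroid_is_zero(self):
        assert dm_gravity(np.tile([3.0, 4.0], (40, 1))) == 0.0

    def test_forty_unit_steps_give_39_mm(self):
        c = np.column_stack([np.zeros(40), np.arange(40.0)])
        assert dm_gravity(c) == pytest.approx(39.0)

    def test_circular_path_chord_sum(self):
        r = 2.5
        th = np.linspace(0, 2 * np.pi, 41)  # back to start in 40 steps
        c = np.column_stack([r * np.cos(th), r * np.sin(th)])
        expect = 40 * 2 * r * np.sin(np.pi / 40)
        assert dm_gravity(c) == pytest.approx(expect, rel=1e-12)
        # chord sum underestimates the circumference by 1 - sinc(pi/40)
        assert expect == pytest.approx(2 * np.pi * r, rel=2e-3)


class TestDgyTrace:
    def test_static_series_all_zero(self):
        assert np.all(dgy_trace(np.tile([1.0, 2.0], (10, 1))) == 0)

    def test_linear_drift(self):
        c = np.column_stack([np.zeros(5), 0.2 * np.arange(5)])
        np.testing.assert_allclose(dgy_trace(c), [0, 0.2, 0.4, 0.6, 0.8])

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(12, 2))
        np.testing.assert_allclose(dgy_trace(c + [5.0, -3.0]), dgy_trace(c))


class TestWallVelocities:
    def test_expanding_circle_normal_velocity(self):
        # radius grows 0.5 mm per frame: outward motion, so the
        # inward-positive normal velocity is -0.5/0.656 = -0.762 mm/s.
        series = _circle_series(10.0 + 0.5 * np.arange(5))
        field = wall_velocities(series)
        np.testing.assert_allclose(field.v_normal, -0.5 / DT, atol=1e-6)
        np.testing.assert_allclose(field.v_tangent, 0.0, atol=1e-6)

    def test_rigid_rotation_tangential_velocity(self):
        r, theta = 15.0, 0.01
        series = _circle_series([r] * 4, rotate_per_frame=theta)
        field = wall_velocities(series)
        np.testing.assert_allclose(field.v_tangent, r * theta / DT, rtol=0.01)
        assert np.max(np.abs(field.v_normal)) < 0.01 * r * theta / DT

    def test_identical_contours_zero_velocities(self):
        series = _circle_series([12.0] * 6)
        field = wall_velocities(series)
        assert np.all(field.v_normal == 0) and np.all(field.v_tangent == 0)

    def test_decomposition_conserves_speed(self):
        rng = np.random.default_rng(5)
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        frames = []
        for t in range(6):
            r = 20 + 2 * np.sin(3 * th + 0.3 * t) + 0.5 * t
            frames.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        series = ContourSeries(points=np.stack(frames),
                               structure_label="duodenum", frame_interval=DT)
        field = wall_velocities(series)
        disp = np.diff(series.points, axis=0) / DT
        speed_sq = np.einsum("tij,tij->ti", disp, disp)
        np.testing.assert_allclose(field.v_normal ** 2 + field.v_tangent ** 2,
                                   speed_sq, rtol=1e-9)

    def test_translation_invariance_of_indices(self):
        # a constant whole-series translation changes nothing; a per-frame
        # translation leaves DM(A) alone but inflates DM(G).
        base = _circle_series(10 + 0.2 * np.arange(8))
        const = ContourSeries(points=base.points + [7.0, -4.0],
                              structure_label="duodenum", frame_interval=DT)
        from gimotion.metrics import area_series
        assert dm_area(area_series(const)) == pytest.approx(
            dm_area(area_series(base)), rel=1e-9)
        assert dm_gravity(centroid_series(const)) == pytest.approx(
            dm_gravity(centroid_series(base)), abs=1e-9)
        vb = dm_velocity(wall_velocities(base))
        vc = dm_velocity(wall_velocities(const))
        assert vc == pytest.approx(vb, rel=1e-9)

        drift = base.points + np.arange(8)[:, None, None] * np.array([0.0, 1.0])
        drifted = ContourSeries(points=drift, structure_label="duodenum",
                                frame_interval=DT)
        assert dm_gravity(centroid_series(drifted)) > dm_gravity(
            centroid_series(base))
        assert dm_area(area_series(drifted)) == pytest.approx(
            dm_area(area_series(base)), rel=1e-9)


class TestDmVelocity:
    def test_constant_field(self):
        from gimotion.core import VelocityField
        f = VelocityField(v_normal=np.full((3, 10), 2.0),
                          v_tangent=np.zeros((3, 10)), frame_interval=DT)
        assert dm_velocity(f) == (2.0, 0.0)

    def test_absolute_values_prevent_cancellation(self):
        from gimotion.core import VelocityField
        vn = np.concatenate([np.ones(50), -np.ones(50)]).reshape(1, 100)
        f = VelocityField(v_normal=vn, v_tangent=np.zeros_like(vn),
                          frame_interval=DT)
        assert dm_velocity(f)[0] == 1.0


class TestGastricResidual:
    def test_identical_scans_all_100(self):
        areas = {s: {p: np.full(40, 50.0 + p) for p in (1, 2, 3, 4)}
                 for s in ("MS1", "MS2", "MS3")}
        gvi = gastric_residual(areas)
        assert gvi.percent == {"MS1": 100.0, "MS2": 100.0, "MS3": 100.0}

    def test_halved_areas_give_50_percent(self):
        ms1 = {p: np.full(40, 60.0) for p in (1, 2)}
        ms3 = {p: np.full(40, 30.0) for p in (1, 2)}
        gvi = gastric_residual({"MS1": ms1, "MS3": ms3})
        assert gvi.percent["MS3"] == pytest.approx(50.0)
        assert gvi.percent["MS1"] == 100.0

    def test_missing_plane_rejected(self):
        with pytest.raises(ValueError, match="planes"):
            gastric_residual({"MS1": {1: np.ones(4), 2: np.ones(4)},
                              "MS2": {1: np.ones(4)}})


class TestComparePaired:
    def test_swapping_conditions_negates_t(self):
        a = [84.0, 90.0, 70.0, 88.0]
        b = [73.0, 80.0, 75.0, 60.0]
        r1, r2 = compare_paired(a, b), compare_paired(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_textbook_formula_oracle(self):
        # differences 1,2,3,4: t = mean / (sd/sqrt(n)) with 3 df, p from
        # the t distribution's survival function.
        from scipy.stats import t as tdist
        b = np.array([10.0, 20.0, 30.0, 40.0])
        a = b + np.array([1.0, 2.0, 3.0, 4.0])
        d = a - b
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        p_expect = 2 * tdist.sf(abs(t_expect), df=3)
        res = compare_paired(a, b)
        assert res.t == pytest.approx(t_expect, rel=1e-12)
        assert res.p == pytest.approx(p_expect, rel=1e-12)
        assert res.n == 4

    def test_identical_samples_degenerate(self):
        res = compare_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p == 1.0 and res.t == 0.0
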