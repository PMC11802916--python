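"""Tracking, persistence, polarity, CIL, edge dynamics and 3D shape."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hemoflow as hf
from hemoflow import synthetic as syn
from hemoflow.datatypes import ParameterizationError, UndefinedResultError
from hemoflow.morphodynamics import EdgeDynamics, EdgeFrame


def _disk_masks(centers_px, n=64, r=5, pixel_size=0.2):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    masks = np.stack([np.hypot(xx - cx, yy - cy) <= r for cx, cy in centers_px])
    return hf.MaskSeries(masks, pixel_size, frame_interval=10.0)


class TestTrackCentroids:
    def test_static_disk_constant(self):
        masks = _disk_masks([(30, 30)] * 3)
        track = hf.track_centroids(masks)
        assert np.ptp(track.x) == 0 and np.ptp(track.y) == 0

    def test_translating_disk_steps(self):
        masks = _disk_masks([(20, 30), (21, 30), (22, 30)])
        track = hf.track_centroids(masks)
        np.testing.assert_allclose(np.diff(track.x), 0.2, atol=1e-9)
        np.testing.assert_allclose(np.diff(track.y), 0.0, atol=1e-9)

    def test_asymmetric_blob_matches_pixel_average(self):
        mask = np.zeros((1, 20, 20), bool)
        mask[0, 3:7, 2:12] = True
        mask[0, 7:12, 2:5] = True
        ms = hf.MaskSeries(np.repeat(mask, 2, axis=0), 0.5)
        track = hf.track_centroids(ms)
        rows, cols = np.nonzero(mask[0])
        assert track.x[0] == pytest.approx(cols.mean() * 0.5)
        assert track.y[0] == pytest.approx(rows.mean() * 0.5)

    def test_multiple_components_named_frame(self):
        masks = np.zeros((2, 20, 20), bool)
        masks[:, 2:5, 2:5] = True
        masks[1, 10:13, 10:13] = True
        with pytest.raises(ParameterizationError, match="frame 1"):
            hf.track_centroids(hf.MaskSeries(masks, 0.2))


class TestMeanSpeed:
    def test_straight_and_stationary(self):
        track, _ = syn.make_track(syn.MotionModel("straight", speed=4.2), 10, 10.0)
        assert hf.mean_speed(track) == pytest.approx(4.2)
        still = hf.Track(t=np.arange(5.0) * 10, x=np.zeros(5), y=np.zeros(5))
        assert hf.mean_speed(still) == 0.0

    def test_prw_recovers_step_speed(self):
        track, _ = syn.make_track(
            syn.MotionModel("persistent_random_walk", speed=3.0,
                            rotational_diffusion=0.05),
            60, 10.0, seed=2,
        )
        assert hf.mean_speed(track) == pytest.approx(3.0, rel=0.05)


class TestPersistence:
    def test_straight_line_every_window_one(self):
        track, _ = syn.make_track(syn.MotionModel("straight", speed=3.0), 30, 10.0)
        values, mean = hf.persistence(track, 60.0)
        assert values.size == 25
        assert np.all(values == 1.0)
        assert mean == 1.0

    def test_out_and_back_window_zero(self):
        t = np.arange(7.0) * 10.0
        x = np.array([0.0, 1, 2, 3, 2, 1, 0])
        track = hf.Track(t=t, x=x, y=np.zeros(7))
        values, _ = hf.persistence(track, 60.0)
        assert values[0] == 0.0

    def test_high_turning_prw_less_persistent_than_straight(self):
        """Monte-Carlo ordering over 100 seeds; heavy turning also drops the
        long-window mean below 0.5."""
        prw_means = []
        for seed in range(100):
            track, _ = syn.make_track(
                syn.MotionModel("persistent_random_walk", speed=3.0,
                                rotational_diffusion=2.0),
                60, 10.0, seed=seed,
            )
            prw_means.append(hf.persistence(track, 300.0)[1])
        assert np.mean(prw_means) < 0.5
        straight, _ = syn.make_track(syn.MotionModel("straight", speed=3.0),
                                     60, 10.0)
        assert hf.persistence(straight, 300.0)[1] > np.mean(prw_means)

    @given(seed=st.integers(0, 10_000))
    def test_bounded_in_unit_interval(self, seed):
        track, _ = syn.make_track(
            syn.MotionModel("persistent_random_walk", speed=3.0,
                            rotational_diffusion=0.5),
            20, 10.0, seed=seed,
        )
        values, _ = hf.persistence(track, 60.0)
        assert np.all(values > 0) and np.all(values <= 1.0)

    def test_short_track_rejected(self):
        track = hf.Track(t=np.array([0.0, 10.0]), x=np.array([0.0, 1.0]),
                         y=np.zeros(2))
        with pytest.raises(ParameterizationError):
            hf.persistence(track, 60.0)


class TestLamellarPolarity:
    def test_disk_centered_on_nucleus_is_one(self):
        masks = _disk_masks([(30, 30)] * 4, r=10)
        nuc = hf.Track(t=np.arange(4.0) * 10,
                       x=np.array([6.0, 6.2, 6.4, 6.6]),
                       y=np.full(4, 6.0))
        # keep the disk centered at the nucleus each frame
        masks = _disk_masks([(30, 30), (31, 30), (32, 30), (33, 30)], r=10)
        per_frame, mean = hf.lamellar_polarity(masks, nuc)
        np.testing.assert_allclose(per_frame[:-1], 1.0, atol=0.05)

    def test_forward_offset_disk_above_one(self):
        # disk ahead of the nucleus along +x motion
        masks = _disk_masks([(34, 30), (35, 30), (36, 30)], r=10)
        nuc = hf.Track(t=np.arange(3.0) * 10,
                       x=np.array([5.6, 5.8, 6.0]), y=np.full(3, 6.0))
        _, mean = hf.lamellar_polarity(masks, nuc)
        assert mean > 1.2

    def test_polarity_grows_with_protrusion_area(self):
        means = []
        for extra in (0, 6, 12):
            yy, xx = np.mgrid[0:64, 0:64].astype(float)
            disk = np.hypot(xx - 30, yy - 30) <= 10
            prot = (np.abs(yy - 30) <= 4) & (xx >= 30) & (xx <= 40 + extra)
            masks = np.stack([disk | prot] * 3)
            ms = hf.MaskSeries(masks, 0.2, 10.0)
            nuc = hf.Track(t=np.arange(3.0) * 10, x=np.array([6.0, 6.2, 6.4]),
                           y=np.full(3, 6.0))
            means.append(hf.lamellar_polarity(ms, nuc)[1])
        assert means[0] < means[1] < means[2]


class TestCILAcceleration:
    def test_uniform_motion_zero(self):
        t = np.arange(13.0) * 10.0
        track = hf.Track(t=t, x=0.3 * t, y=-0.1 * t)
        event = hf.CollisionEvent(track=track, partner_position=(50.0, 0.0),
                                  collision_time=60.0)
        assert hf.cil_acceleration(event) == pytest.approx(0.0, abs=1e-12)

    def test_full_reversal_closed_form(self):
        speed = 3.0  # µm/min
        focal, partner, event, gt = syn.make_collision_pair(
            speed=speed, dt=10.0, n_steps=20, collision_time_index=10,
            reversal=1.0,
        )
        ax = hf.cil_acceleration(event)
        s = speed / 60.0  # µm/s
        assert ax == pytest.approx(-2 * s / 60.0, abs=1e-9)
        assert ax == pytest.approx(gt.params["expected_ax_um_per_s2"], abs=1e-12)
        assert ax < 0

    @given(angle=st.floats(0.0, 2 * math.pi), tx=st.floats(-40, 40),
           ty=st.floats(-40, 40))
    def test_rotation_translation_invariance(self, angle, tx, ty):
        focal, partner, event, _ = syn.make_collision_pair(
            speed=3.0, dt=10.0, n_steps=20, collision_time_index=10,
            reversal=0.7,
        )
        base = hf.cil_acceleration(event)
        c, s = math.cos(angle), math.sin(angle)
        rx = c * focal.x - s * focal.y + tx
        ry = s * focal.x + c * focal.y + ty
        px, py = event.partner_position
        rot_event = hf.CollisionEvent(
            track=hf.Track(t=focal.t, x=rx, y=ry),
            partner_position=(c * px - s * py + tx, s * px + c * py + ty),
            collision_time=event.collision_time,
        )
        assert hf.cil_acceleration(rot_event) == pytest.approx(base, abs=1e-9)

    def test_coincident_partner_rejected(self):
        t = np.arange(13.0) * 10.0
        track = hf.Track(t=t, x=0.1 * t, y=np.zeros(13))
        event = hf.CollisionEvent(track=track, partner_position=(6.0, 0.0),
                                  collision_time=60.0)
        with pytest.raises(UndefinedResultError):
            hf.cil_acceleration(event)


class TestEdgeDynamics:
    def test_static_mask_zero_speeds(self):
        masks, gt = syn.make_mask_sequence(protrusions=[], n_frames=3)
        c = gt.params["center_x_um"]
        nuc = hf.Track(t=10.0 * np.arange(3), x=np.full(3, c), y=np.full(3, c))
        dyn = hf.edge_dynamics(masks, nuc)
        for ef in dyn:
            assert ef.largest_extension_speed == 0.0
            assert np.abs(ef.boundary_speeds).max() < 0.06  # sub-pixel jitter

    def test_single_sector_speed_and_direction(self):
        masks, gt = syn.make_mask_sequence(
            base_radius=8.0, protrusions=[(0.0, 60.0, 1.0)], n_frames=5,
            pixel_size=0.2, frame_interval=10.0,
        )
        c = gt.params["center_x_um"]
        nuc = hf.Track(t=10.0 * np.arange(5), x=np.full(5, c), y=np.full(5, c))
        dyn = hf.edge_dynamics(masks, nuc)
        for ef in dyn:
            assert ef.valid
            assert ef.largest_extension_speed == pytest.approx(
                gt.params["growth_um_per_s"], rel=0.10
            )
            ex, ey = ef.extension_vector
            angle = math.degrees(math.atan2(-ey, ex))
            assert abs(angle - gt.params["largest_sector_bisector_deg"]) < 10.0

    def test_largest_extension_bounded_by_max_boundary_speed(self):
        masks, gt = syn.make_mask_sequence(
            protrusions=[(45.0, 90.0, 0.6)], n_frames=4, pixel_size=0.2
        )
        c = gt.params["center_x_um"]
        nuc = hf.Track(t=10.0 * np.arange(4), x=np.full(4, c), y=np.full(4, c))
        for ef in hf.edge_dynamics(masks, nuc):
            assert ef.largest_extension_speed <= ef.boundary_speeds.max() + 1e-12

    def test_two_sectors_larger_difference_area_selected(self):
        masks, gt = syn.make_mask_sequence(
            protrusions=[(0.0, 40.0, 0.5), (120.0, 80.0, 0.8)], n_frames=3,
            pixel_size=0.2,
        )
        c = gt.params["center_x_um"]
        nuc = hf.Track(t=10.0 * np.arange(3), x=np.full(3, c), y=np.full(3, c))
        for ef in hf.edge_dynamics(masks, nuc):
            ex, ey = ef.extension_vector
            angle = math.degrees(math.atan2(-ey, ex))
            assert abs(angle - 120.0) < 15.0


class TestMotionExtensionCorrelation:
    @staticmethod
    def _dyn(pairs):
        frames = [
            EdgeFrame(i, np.zeros(1), 0.1, 0.1, m, e, True)
            for i, (m, e) in enumerate(pairs)
        ]
        return EdgeDynamics(frames)

    def test_aligned_perpendicular_opposed(self):
        dyn = self._dyn([((1.0, 0.0), (2.0, 0.0)), ((0.0, 1.0), (1.0, 0.0)),
                         ((1.0, 0.0), (-3.0, 0.0))])
        cos, mean, hist, edges = hf.motion_extension_correlation(dyn)
        np.testing.assert_allclose(cos, [1.0, 0.0, -1.0], atol=1e-12)
        # fully aligned frame lands in the bin containing 0°
        zero_bin = np.searchsorted(edges, 0.0, side="right") - 1
        assert hist[zero_bin] >= 1

    def test_decorrelated_angles_average_near_zero(self):
        rng = np.random.default_rng(0)
        pairs = []
        for _ in range(100):
            th = rng.uniform(0, 2 * np.pi)
            pairs.append(((1.0, 0.0), (math.cos(th), math.sin(th))))
        _, mean, _, _ = hf.motion_extension_correlation(self._dyn(pairs))
        assert abs(mean) < 0.1

    def test_no_defined_frames_raises(self):
        dyn = EdgeDynamics([EdgeFrame(0, np.zeros(1), 0.0, 0.0, None, None, False)])
        with pytest.raises(UndefinedResultError):
            hf.motion_extension_correlation(dyn)


class TestShapeMetrics:
    def test_sphere_sphericity_near_one(self):
        mask, _ = syn.make_ellipsoid_mask((5.0, 5.0, 5.0), 0.25)
        m = hf.shape_metrics(mask, 0.25)
        assert m["sphericity"] == pytest.approx(1.0, rel=0.02)

    def test_ellipsoid_volume_closed_form(self):
        mask, gt = syn.make_ellipsoid_mask((8.0, 4.0, 2.0), 0.25)
        m = hf.shape_metrics(mask, 0.25)
        assert m["volume_um3"] == pytest.approx(gt.params["volume_um3"], rel=0.02)

    def test_oblate_less_spherical_than_sphere(self):
        sphere, _ = syn.make_ellipsoid_mask((5.0, 5.0, 5.0), 0.25)
        oblate, _ = syn.make_ellipsoid_mask((6.0, 6.0, 2.5), 0.25)
        s1 = hf.shape_metrics(sphere, 0.25)["sphericity"]
        s2 = hf.shape_metrics(oblate, 0.25)["sphericity"]
        assert s2 < s1

    def test_lamellar_volume_and_subset_check(self):
        mask, _ = syn.make_ellipsoid_mask((5.0, 5.0, 5.0), 0.5)
        m = hf.shape_metrics(mask, 0.5, body_mask3d=mask)
        assert m["lamellar_volume_um3"] == 0.0
        body = np.zeros_like(mask)
        body[0, 0, 0] = True
        with pytest.raises(ParameterizationError):
            hf.shape_metrics(mask, 0.5, body_mask3d=body)
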