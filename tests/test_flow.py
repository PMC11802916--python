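"""PIV measurement and flow post-processing."""

import numpy as np
import pytest

import hemoflow as hf
from hemoflow import synthetic as syn
from hemoflow.datatypes import ParameterizationError, UndefinedResultError

PX_TO_UM_MIN = 0.1 / 5.0 * 60.0  # px/frame -> µm/min at 0.1 µm/px, 5 s


def brute_force_piv(frames, params, pixel_size):
    """Independent exhaustive integer-displacement ZNCC search (oracle)."""
    w = int(round(np.sqrt(params.window_area) / pixel_size))
    search = int(round(np.sqrt(params.search_area) / pixel_size))
    m = max((search - w) // 2, 1)
    step = w - int(round(params.window_overlap / pixel_size))
    h, wid = frames.shape[-2:]
    rows0 = np.arange(0, h - w + 1, step)
    cols0 = np.arange(0, wid - w + 1, step)
    out = {}
    for t in range(frames.shape[0] - 1):
        for i, r0 in enumerate(rows0):
            for j, c0 in enumerate(cols0):
                src = frames[t, r0 : r0 + w, c0 : c0 + w]
                sc = src - src.mean()
                sn = np.sqrt((sc**2).sum())
                if sn == 0:
                    continue
                best, best_c = None, -np.inf
                for dy in range(-m, m + 1):
                    for dx in range(-m, m + 1):
                        rr, cc = r0 + dy, c0 + dx
                        if rr < 0 or cc < 0 or rr + w > h or cc + w > wid:
                            continue
                        tgt = frames[t + 1, rr : rr + w, cc : cc + w]
                        tc = tgt - tgt.mean()
                        tn = np.sqrt((tc**2).sum())
                        if tn == 0:
                            continue
                        c = float((sc * tc).sum() / (sn * tn))
                        if c > best_c:
                            best, best_c = (dy, dx), c
                if best is not None:
                    out[(t, i, j)] = (best, best_c)
    return out


class TestComputePIV:
    @pytest.mark.parametrize("mag", [0.5, 1.0, 2.0])
    def test_translation_recovery(self, piv_params, mag):
        """Noiseless translations recovered to <= 0.2 px/frame median error."""
        movie, _ = syn.make_speckle_movie(
            "uniform", mag, frame_size=(64, 64), pixel_size=0.1, n_frames=4,
            frame_interval=5.0, seed=7,
        )
        field = hf.compute_piv(movie, None, piv_params)
        assert field.valid.sum() > 100
        u_px = field.u[field.valid] / PX_TO_UM_MIN
        v_px = field.v[field.valid] / PX_TO_UM_MIN
        assert np.median(np.abs(u_px - mag)) <= 0.2
        assert np.median(np.abs(v_px)) <= 0.2

    def test_matches_brute_force_oracle(self, piv_params):
        """Integer-peak equivalence with an exhaustive search on a tiny movie."""
        movie, _ = syn.make_speckle_movie(
            "uniform", 1.0, frame_size=(16, 16), pixel_size=0.1, n_frames=3,
            frame_interval=5.0, speckle_density=0.15, seed=11,
        )
        field = hf.compute_piv(movie, None, piv_params)
        oracle = brute_force_piv(movie.frames, piv_params, 0.1)
        checked = 0
        for (t, i, j), ((dy, dx), corr) in oracle.items():
            if not field.valid[t, i, j]:
                assert corr <= piv_params.corr_threshold
                continue
            assert field.corr[t, i, j] == pytest.approx(corr, abs=1e-12)
            assert abs(field.u[t, i, j] / PX_TO_UM_MIN - dx) <= 0.5 + 1e-9
            assert abs(field.v[t, i, j] / PX_TO_UM_MIN - dy) <= 0.5 + 1e-9
            checked += 1
        assert checked >= 4

    def test_strict_threshold_invalidates_noisy_nodes(self, piv_params):
        movie, _ = syn.make_speckle_movie(
            "uniform", 2.0, frame_size=(64, 64), pixel_size=0.1, n_frames=3,
            frame_interval=5.0, noise_sd=0.01, seed=5,
        )
        loose = hf.compute_piv(movie, None, piv_params)
        strict_p = hf.PIVParams(
            window_area=0.64, window_overlap=0.4, search_area=2.56,
            corr_threshold=0.999,
        )
        strict = hf.compute_piv(movie, None, strict_p)
        assert loose.valid.mean() > 0.8
        assert strict.valid.sum() <= 0.1 * loose.valid.sum()

    def test_solid_rotation_angular_speed(self, piv_params):
        omega = 0.02  # rad/frame
        movie, _ = syn.make_speckle_movie(
            "rotation", omega, frame_size=(80, 80), pixel_size=0.1, n_frames=5,
            frame_interval=5.0, seed=3,
        )
        field = hf.compute_piv(movie, None, piv_params)
        c = (80 - 1) / 2 * 0.1
        xx, yy = np.meshgrid(field.x, field.y)
        A, b = [], []
        for t in range(field.n_frames):
            sel = field.valid[t]
            A.append(np.concatenate([-(yy[sel] - c), xx[sel] - c]))
            b.append(np.concatenate([field.u[t][sel], field.v[t][sel]]))
        A, b = np.concatenate(A), np.concatenate(b)
        omega_fit = (A @ b) / (A @ A)  # rad/min
        assert omega_fit == pytest.approx(omega / 5.0 * 60.0, rel=0.06)

    def test_empty_mask_frame_all_invalid(self, translation_movie, piv_params):
        movie, _ = translation_movie
        masks = hf.MaskSeries(
            np.zeros((movie.n_frames, *movie.frame_shape), bool), 0.1
        )
        with pytest.warns(UserWarning, match="empty mask"):
            field = hf.compute_piv(movie, masks, piv_params)
        assert not field.valid.any()

    def test_window_larger_than_frame_rejected(self, piv_params):
        movie = hf.Movie(
            np.zeros((2, 6, 6)), ["c"], pixel_size=0.1, frame_interval=1.0
        )
        with pytest.raises(ParameterizationError):
            hf.compute_piv(movie, None, piv_params)


class TestInterpolateFlow:
    def _field(self, u, v, valid, spacing=1.0):
        n = u.shape[-1]
        x = np.arange(n, dtype=float) * spacing
        return hf.FlowField(x=x, y=x, u=u, v=v, valid=valid,
                            grid_spacing=spacing, frame_interval=10.0)

    def test_constant_field_unchanged(self):
        u = np.full((6, 9, 9), 2.5)
        f = self._field(u, -u, np.ones_like(u, bool))
        out = hf.interpolate_flow(f)
        np.testing.assert_allclose(out.u, 2.5, atol=1e-9)
        np.testing.assert_allclose(out.v, -2.5, atol=1e-9)

    def test_single_valid_node_spreads_value(self):
        u = np.zeros((5, 9, 9))
        valid = np.zeros_like(u, bool)
        u[2, 4, 4] = 3.0
        valid[2, 4, 4] = True
        out = hf.interpolate_flow(self._field(u, np.zeros_like(u), valid))
        assert out.valid.sum() > 1
        # the sole contributor fixes the value everywhere in its support
        np.testing.assert_allclose(out.u[out.valid], 3.0, atol=1e-9)
        assert out.valid[2, 4, 4]

    def test_checkerboard_amplitude_contracts(self):
        n = 9
        cb = (np.indices((n, n)).sum(axis=0) % 2) * 2.0 - 1.0
        v = np.broadcast_to(cb, (5, n, n)).copy()
        out = hf.interpolate_flow(self._field(np.zeros_like(v), v,
                                              np.ones_like(v, bool)))
        assert np.abs(out.v).max() < 1.0

    def test_never_increases_max_magnitude(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(6, 9, 9))
        v = rng.normal(size=(6, 9, 9))
        valid = rng.random((6, 9, 9)) > 0.3
        f = self._field(u, v, valid)
        out = hf.interpolate_flow(f)
        max_in = np.hypot(u, v)[valid].max()
        max_out = np.hypot(out.u, out.v)[out.valid].max()
        assert max_out <= max_in + 1e-9

    def test_all_invalid_stays_invalid(self):
        u = np.zeros((5, 9, 9))
        out = hf.interpolate_flow(self._field(u, u, np.zeros_like(u, bool)))
        assert not out.valid.any()


class TestMeanFlowSpeed:
    def test_uniform_field(self, linear_sink_field):
        x = np.arange(5, dtype=float)
        u = np.full((2, 5, 5), 3.0)
        f = hf.FlowField(x=x, y=x, u=u, v=np.zeros_like(u),
                         valid=np.ones_like(u, bool), grid_spacing=1.0,
                         frame_interval=5.0)
        assert hf.mean_flow_speed(f) == pytest.approx(3.0)

    def test_mixed_magnitudes_average(self):
        x = np.arange(4, dtype=float)
        u = np.zeros((1, 4, 4))
        u[0, :2] = 2.0  # half at 2s, half at 0
        f = hf.FlowField(x=x, y=x, u=u, v=np.zeros_like(u),
                         valid=np.ones_like(u, bool), grid_spacing=1.0,
                         frame_interval=5.0)
        assert hf.mean_flow_speed(f) == pytest.approx(1.0)

    def test_sink_field_matches_analytic_mean(self):
        # |v| = a*r on a fine node grid vs numerical integration of the
        # analytic field over the same extent
        a = 0.05
        x = np.arange(0.0, 10.01, 0.25)
        xx, yy = np.meshgrid(x, x)
        u = (-a * (xx - 5.0))[None]
        v = (-a * (yy - 5.0))[None]
        field = hf.FlowField(x=x, y=x, u=u, v=v,
                             valid=np.ones_like(u, bool), grid_spacing=0.25,
                             frame_interval=5.0)
        g = np.linspace(0, 10, 801)
        gx, gy = np.meshgrid(g, g)
        analytic = np.mean(a * np.hypot(gx - 5, gy - 5))
        assert hf.mean_flow_speed(field) == pytest.approx(analytic, rel=0.05)

    def test_no_valid_nodes_raises(self):
        x = np.arange(4, dtype=float)
        u = np.zeros((1, 4, 4))
        f = hf.FlowField(x=x, y=x, u=u, v=u, valid=np.zeros_like(u, bool),
                         grid_spacing=1.0, frame_interval=5.0)
        with pytest.raises(UndefinedResultError):
            hf.mean_flow_speed(f)


class TestStreamlines:
    def test_uniform_field_straight_lines(self):
        x = np.arange(11, dtype=float)
        u = np.full((2, 11, 11), 2.0)
        f = hf.FlowField(x=x, y=x, u=u, v=np.zeros_like(u),
                         valid=np.ones_like(u, bool), grid_spacing=1.0,
                         frame_interval=5.0)
        (line,) = hf.streamlines(f, [(1.0, 5.0)], step=0.5)
        assert np.ptp(line[:, 1]) < 1e-9
        assert line[-1, 0] > 9.0

    def test_solid_rotation_closes_onto_circle(self):
        x = np.arange(11, dtype=float)
        xx, yy = np.meshgrid(x, x)
        w = 0.5
        u = (-w * (yy - 5))[None]
        v = (w * (xx - 5))[None]
        f = hf.FlowField(x=x, y=x, u=u, v=v, valid=np.ones_like(u, bool),
                         grid_spacing=1.0, frame_interval=5.0)
        (line,) = hf.streamlines(f, [(7.0, 5.0)], step=0.05, max_steps=500)
        r = np.hypot(line[:, 0] - 5, line[:, 1] - 5)
        np.testing.assert_allclose(r, 2.0, atol=0.05)
        # returns within one step of the seed after a full revolution
        gaps = np.hypot(line[150:, 0] - 7.0, line[150:, 1] - 5.0)
        assert gaps.min() < 0.05

    def test_sink_field_converges_to_center(self, linear_sink_field):
        field, _ = linear_sink_field
        lines = hf.streamlines(field, [(1.0, 1.0), (9.0, 2.0)], step=0.2,
                               max_steps=2000)
        for line in lines:
            r_start = np.hypot(line[0, 0] - 5, line[0, 1] - 5)
            r_end = np.hypot(line[-1, 0] - 5, line[-1, 1] - 5)
            assert r_end < 0.25 * r_start

    def test_seed_outside_grid_skipped(self, linear_sink_field):
        field, _ = linear_sink_field
        with pytest.warns(UserWarning, match="outside the grid"):
            lines = hf.streamlines(field, [(50.0, 50.0)])
        assert lines == []


class TestDeformationMap:
    def test_zero_field_zero_deformation(self):
        x = np.arange(11, dtype=float)
        u = np.zeros((3, 11, 11))
        f = hf.FlowField(x=x, y=x, u=u, v=u, valid=np.ones_like(u, bool),
                         grid_spacing=1.0, frame_interval=10.0)
        dm = hf.deformation_map(f, 2.0)
        np.testing.assert_allclose(dm.values, 0.0)

    def test_uniform_field_closed_form(self):
        x = np.arange(11, dtype=float)
        u = np.full((6, 11, 11), 3.0)  # µm/min over 6 frames * 10 s = 1 min
        f = hf.FlowField(x=x, y=x, u=u, v=np.zeros_like(u),
                         valid=np.ones_like(u, bool), grid_spacing=1.0,
                         frame_interval=10.0)
        dm = hf.deformation_map(f, 2.0)
        inside = dm.values[0][dm.valid[0]]
        assert inside.size > 0
        np.testing.assert_allclose(inside, 3.0, atol=1e-6)

    def test_sink_deformation_grows_with_radius(self, linear_sink_field):
        field, _ = linear_sink_field
        f10 = hf.FlowField(
            x=field.x, y=field.y,
            u=np.repeat(field.u, 10, axis=0), v=np.repeat(field.v, 10, axis=0),
            valid=np.ones((10, 11, 11), bool), grid_spacing=1.0,
            frame_interval=5.0,
        )
        dm = hf.deformation_map(f10, 1.0)
        gx, gy = np.meshgrid(dm.x, dm.y)
        r = np.hypot(gx - 5, gy - 5)
        ok = dm.valid[0]
        near = dm.values[0][(r < 2) & ok].mean()
        far = dm.values[0][(r > 3.5) & ok].mean()
        assert far > near


class TestCosineSimilarity:
    def _field(self, u, v):
        x = np.arange(u.shape[-1], dtype=float)
        return hf.FlowField(x=x, y=x, u=u, v=v, valid=np.ones_like(u, bool),
                            grid_spacing=1.0, frame_interval=5.0)

    def test_identical_opposite_orthogonal(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(2, 6, 6)) + 2.0
        v = rng.normal(size=(2, 6, 6))
        a = self._field(u, v)
        assert hf.flow_cosine_similarity(a, self._field(u, v))[1] == pytest.approx(1.0)
        assert hf.flow_cosine_similarity(a, self._field(-u, -v))[1] == pytest.approx(-1.0)
        # rotate every vector by 90°
        rot = self._field(-v, u)
        assert hf.flow_cosine_similarity(a, rot)[1] == pytest.approx(0.0, abs=1e-9)

    def test_cosine_bounded(self):
        rng = np.random.default_rng(2)
        a = self._field(rng.normal(size=(3, 5, 5)), rng.normal(size=(3, 5, 5)))
        b = self._field(rng.normal(size=(3, 5, 5)), rng.normal(size=(3, 5, 5)))
        cos, mean = hf.flow_cosine_similarity(a, b)
        finite = cos[np.isfinite(cos)]
        assert np.all(finite >= -1.0) and np.all(finite <= 1.0)
        assert -1.0 <= mean <= 1.0

    def test_no_covalid_nodes_raises(self):
        u = np.ones((1, 5, 5))
        x = np.arange(5, dtype=float)
        a = hf.FlowField(x=x, y=x, u=u, v=u, valid=np.ones_like(u, bool),
                         grid_spacing=1.0, frame_interval=5.0)
        b = hf.FlowField(x=x, y=x, u=u, v=u, valid=np.zeros_like(u, bool),
                         grid_spacing=1.0, frame_interval=5.0)
        with pytest.raises(UndefinedResultError):
            hf.flow_cosine_similarity(a, b)
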