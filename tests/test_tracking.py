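"""Control-volume seeding, advection, mass integration and tracking."""

import numpy as np
import pytest

from lving import (
    Calibration,
    CellMask,
    ControlVolume,
    MassFrame,
    VelocityField,
    advect_control_volume,
    integrate_mass,
    seed_control_volumes,
    track_control_volumes,
)
from lving.tracking import EmptySeedError, is_simple_quad, polygon_area


def _field(u, v, n=9, dt=1.0, spacing=2.0):
    g = np.arange(n) * spacing + 1.0
    return VelocityField(grid_x=g, grid_y=g, u=np.full((n, n), float(u)),
                         v=np.full((n, n), float(v)),
                         valid=np.ones((n, n), bool), dt=dt)


def _square_cv(x0=2.0, y0=2.0, side=1.0, cv_id=0):
    corners = np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])
    return ControlVolume(corners, cv_id, (x0 + side / 2, y0 + side / 2))


class TestSeeding:
    def test_exact_tiling_count(self):
        cal = Calibration(0.25, 1.0)
        mask = np.zeros((48, 48), bool)
        mask[4:44, 4:44] = True  # 10x10 um square
        cvs = seed_control_volumes(CellMask(mask), cal, target_area=1.0)
        assert len(cvs) == 100
        assert all(np.isclose(cv.area, 1.0) for cv in cvs)

    def test_default_area_side_length(self, cal):
        mask = np.zeros((64, 64), bool)
        mask[8:56, 8:56] = True
        cvs = seed_control_volumes(CellMask(mask), cal, target_area=0.7)
        assert np.isclose(cvs[0].area, 0.7)
        side = cvs[0].corners[1, 0] - cvs[0].corners[0, 0]
        assert np.isclose(side, np.sqrt(0.7))

    def test_ids_are_row_major_and_deterministic(self, cal):
        mask = np.zeros((32, 32), bool)
        mask[4:28, 4:28] = True
        a = seed_control_volumes(CellMask(mask), cal, 0.7)
        b = seed_control_volumes(CellMask(mask), cal, 0.7)
        assert [cv.id for cv in a] == list(range(len(a)))
        assert all(np.array_equal(x.corners, y.corners) for x, y in zip(a, b))
        centers = np.array([cv.seed_center for cv in a])
        assert np.all(np.diff(centers[:, 1]) >= -1e-9)  # rows scan downward

    def test_empty_mask_errors(self, cal):
        with pytest.raises(EmptySeedError):
            seed_control_volumes(CellMask(np.zeros((16, 16), bool)), cal, 0.7)

    def test_target_smaller_than_pixel_errors(self, cal):
        mask = CellMask(np.ones((16, 16), bool))
        with pytest.raises(ValueError):
            seed_control_volumes(mask, cal, target_area=0.01)


class TestAdvection:
    def test_zero_field_leaves_corners(self):
        cv = _square_cv()
        out, ok = advect_control_volume(cv, _field(0, 0), 1.0)
        assert ok and np.allclose(out.corners, cv.corners)

    def test_uniform_field_translates_rigidly(self):
        cv = _square_cv()
        out, ok = advect_control_volume(cv, _field(1.0, 0.0), 1.0)
        assert ok
        assert np.allclose(out.corners, cv.corners + [1.0, 0.0])
        assert np.isclose(out.area, cv.area)

    def test_linear_shear_gives_analytic_parallelogram(self):
        # u = k*y, v = 0 on the node grid
        n = 9
        g = np.arange(n) * 2.0 + 1.0
        xx, yy = np.meshgrid(g, g)
        k = 0.1
        field = VelocityField(grid_x=g, grid_y=g, u=k * yy, v=np.zeros((n, n)),
                              valid=np.ones((n, n), bool), dt=1.0)
        cv = _square_cv(4.0, 4.0, 2.0)
        out, ok = advect_control_volume(cv, field, 1.0)
        expected = cv.corners + np.column_stack(
            [k * cv.corners[:, 1], np.zeros(4)])
        assert ok
        assert np.allclose(out.corners, expected, atol=1e-12)
        assert np.isclose(out.area, cv.area, atol=1e-12)

    def test_exit_flags_out_of_bounds(self):
        cv = _square_cv(1.0, 1.0)
        out, ok = advect_control_volume(cv, _field(-5.0, 0.0), 1.0, image_extent=(10.0, 10.0))
        assert not ok and out is None

    def test_rk2_matches_euler_on_uniform_field(self):
        cv = _square_cv()
        a, _ = advect_control_volume(cv, _field(0.5, -0.5), 2.0, scheme="euler")
        b, _ = advect_control_volume(cv, _field(0.5, -0.5), 2.0, scheme="rk2")
        assert np.allclose(a.corners, b.corners)


class TestQuadGeometry:
    def test_simple_and_twisted_quads(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        assert is_simple_quad(square)
        assert not is_simple_quad(bowtie)

    def test_ccw_area_positive(self):
        square = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        assert polygon_area(square) == 4.0
        assert polygon_area(square[::-1]) == -4.0


class TestIntegrateMass:
    def test_uniform_density_gives_sigma_times_area(self, cal):
        frame = MassFrame(np.ones((64, 64)), 0.0, cal)
        side = np.sqrt(0.7)
        cv = _square_cv(3.1, 4.2, side)
        assert abs(integrate_mass(cv, frame) - 0.7) < 1e-3

    def test_background_polygon_is_zero(self, cal):
        frame = MassFrame(np.zeros((64, 64)), 0.0, cal)
        assert integrate_mass(_square_cv(3.0, 3.0), frame) == 0.0

    def test_tiling_additivity(self, textured_frame):
        side = 0.8
        left = _square_cv(5.0, 5.0, side)
        right = _square_cv(5.0 + side, 5.0, side)
        both = ControlVolume(
            np.array([[5.0, 5.0], [5.0 + 2 * side, 5.0],
                      [5.0 + 2 * side, 5.0 + side], [5.0, 5.0 + side]]),
            9, (0, 0))
        total = integrate_mass(both, textured_frame)
        assert abs(integrate_mass(left, textured_frame)
                   + integrate_mass(right, textured_frame) - total) < 2e-3

    def test_clip_and_supersample_agree(self, textured_frame, rng):
        side = np.sqrt(0.7)
        for _ in range(10):
            x0, y0 = rng.uniform(8, 20, 2)
            corners = np.array([[x0, y0], [x0 + side, y0],
                                [x0 + side, y0 + side], [x0, y0 + side]])
            corners = corners + rng.normal(0, 0.08, (4, 2))
            if polygon_area(corners) < 0:
                corners = corners[::-1]
            a = integrate_mass(corners, textured_frame, "clip")
            b = integrate_mass(corners, textured_frame, "supersample", subsamples=64)
            assert abs(a - b) < 1e-3

    def test_degenerate_polygon_is_zero(self, textured_frame):
        line = np.array([[5, 5], [6, 5], [6, 5], [5, 5]], float)
        assert integrate_mass(line, textured_frame) == 0.0

    def test_translation_preserves_mass_on_uniform_field(self, cal):
        frame = MassFrame(np.full((64, 64), 1.3), 0.0, cal)
        cv = _square_cv(4.0, 4.0, np.sqrt(0.7))
        m0 = integrate_mass(cv, frame)
        shifted = ControlVolume(cv.corners + [0.37, 0.61], 1, cv.seed_center)
        assert abs(integrate_mass(shifted, frame) - m0) < 1e-3


class TestTracking:
    def _static_movie(self, textured_frame, cal, n=5):
        frames = [MassFrame(textured_frame.density, k * 1.0, cal) for k in range(n)]
        fields = [_field(0, 0, n=15, spacing=2.0) for _ in range(n - 1)]
        return frames, fields

    def test_static_movie_constant_mass(self, textured_frame, cal):
        frames, fields = self._static_movie(textured_frame, cal)
        from lving import segment_cell

        cvs = seed_control_volumes(segment_cell(frames[0]), cal, 0.7)
        tracks = track_control_volumes(frames, fields, cvs, anchored=False)
        for t in tracks:
            assert np.allclose(t.masses, t.masses[0], atol=1e-9)
            assert t.in_bounds.all()

    def test_anchored_static_movie_constant_mass(self, textured_frame, cal):
        frames, fields = self._static_movie(textured_frame, cal)
        from lving import segment_cell

        cvs = seed_control_volumes(segment_cell(frames[0]), cal, 0.7)
        tracks = track_control_volumes(frames, fields, cvs, anchored=True)
        for t in tracks:
            assert np.allclose(t.masses, t.masses[0], atol=5e-3)

    def test_length_mismatch_errors(self, textured_frame, cal):
        frames, fields = self._static_movie(textured_frame, cal)
        with pytest.raises(ValueError):
            track_control_volumes(frames, fields[:-1], [])

    def test_rigid_translation_conserves_track_mass(self, textured_frame, cal):
        # frames rigidly rolled by 1 px/frame, prescribed uniform field
        n = 6
        frames = [
            MassFrame(np.roll(textured_frame.density, k, axis=1), k * 1.0, cal)
            for k in range(n)
        ]
        fields = [_field(cal.pixel_size, 0.0, n=15, spacing=2.0) for _ in range(n - 1)]
        from lving import segment_cell

        cvs = seed_control_volumes(segment_cell(frames[0]), cal, 0.7)
        tracks = track_control_volumes(frames, fields, cvs, anchored=False)
        for t in tracks:
            if t.in_bounds.all():
                assert np.max(np.abs(t.masses - t.masses[0])) < 0.02 * max(t.masses[0], 0.1)
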