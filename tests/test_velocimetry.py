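"""Window correlation, vector validation and interpolation."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from lving import (
    MassFrame,
    PIVConfig,
    VelocityField,
    compute_velocity_field,
    correlate_window,
    interpolate_velocity,
    median_filter_vectors,
    segment_cell,
)
from lving.velocimetry import InsufficientVectorsError, anchored_displacement


def _uniform_field(u=1.0, v=0.0, n=5, dt=1.0):
    g = np.arange(n, dtype=float) + 1.0
    return VelocityField(
        grid_x=g, grid_y=g,
        u=np.full((n, n), u), v=np.full((n, n), v),
        valid=np.ones((n, n), bool), dt=dt,
    )


class TestCorrelateWindow:
    def test_identical_windows_give_zero(self, textured_frame):
        win = textured_frame.density[40:72, 40:72]
        dx, dy, q = correlate_window(win, win, 4)
        assert abs(dx) < 1e-3 and abs(dy) < 1e-3
        assert q > 1.2

    @settings(derandomize=True, max_examples=20,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(dy=st.integers(-3, 3), dx=st.integers(-3, 3))
    def test_integer_roll_exact(self, textured_frame, dy, dx):
        win = textured_frame.density[40:72, 40:72]
        rolled = np.roll(win, (dy, dx), axis=(0, 1))
        mx, my, _ = correlate_window(win, rolled, 4, subpixel=False)
        assert (mx, my) == (dx, dy)

    def test_subpixel_shift_rms(self, textured_frame):
        from scipy.ndimage import fourier_shift

        dens = textured_frame.density
        shifted = np.real(np.fft.ifft2(fourier_shift(np.fft.fft2(dens), (0.0, 0.30))))
        errs = []
        for top in range(32, 80, 8):
            for left in range(32, 80, 8):
                if dens[top : top + 32, left : left + 32].mean() < 0.3:
                    continue
                dx, dy, _ = correlate_window(
                    dens[top : top + 32, left : left + 32],
                    shifted[top : top + 32, left : left + 32],
                    4,
                )
                errs.append((dx - 0.30) ** 2 + dy**2)
        assert np.sqrt(np.mean(errs)) <= 0.05

    def test_flat_window_flags_invalid(self):
        flat = np.ones((32, 32))
        dx, dy, q = correlate_window(flat, flat, 4)
        assert np.isnan(dx) and np.isnan(dy) and q == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            correlate_window(np.ones((16, 16)), np.ones((16, 8)), 2)


class TestComputeVelocityField:
    def test_no_motion_gives_zero_vectors(self, textured_frame, cal):
        b = MassFrame(textured_frame.density, 1.0, cal)
        mask = segment_cell(textured_frame)
        field = compute_velocity_field(textured_frame, b, mask)
        assert field.valid.any()
        assert np.max(np.abs(field.u[field.valid])) < 0.01
        assert np.max(np.abs(field.v[field.valid])) < 0.01

    def test_rigid_translation_recovered(self, textured_frame, cal):
        rolled = np.roll(textured_frame.density, 1, axis=1)  # +1 px in x
        b = MassFrame(rolled, 1.0, cal)
        mask = segment_cell(textured_frame)
        field = compute_velocity_field(textured_frame, b, mask)
        on = field.speed > 0.5 * cal.pixel_size  # nodes carrying signal
        assert on.any()
        assert np.allclose(field.u[on], cal.pixel_size, atol=0.05 * cal.pixel_size)
        assert np.allclose(field.v[on], 0.0, atol=0.05 * cal.pixel_size)

    def test_antisymmetric_under_frame_swap(self, textured_frame, cal):
        rolled = np.roll(textured_frame.density, 1, axis=1)
        b = MassFrame(rolled, 1.0, cal)
        b0 = MassFrame(textured_frame.density, 0.0, cal)
        b_at_0 = MassFrame(rolled, 0.0, cal)
        fwd_frame_b = MassFrame(rolled, 1.0, cal)
        mask = segment_cell(textured_frame)
        fwd = compute_velocity_field(b0, fwd_frame_b, mask)
        rev = compute_velocity_field(b_at_0, MassFrame(textured_frame.density, 1.0, cal), mask)
        sel = fwd.valid & rev.valid & (fwd.speed > 0.5 * cal.pixel_size)
        assert np.allclose(fwd.u[sel], -rev.u[sel], atol=0.05 * cal.pixel_size)

    def test_speed_bounded_by_search_radius(self, textured_frame, cal):
        rolled = np.roll(textured_frame.density, 2, axis=0)
        field = compute_velocity_field(
            textured_frame, MassFrame(rolled, 1.0, cal), segment_cell(textured_frame)
        )
        bound = PIVConfig().search_radius * cal.pixel_size / field.dt
        assert np.nanmax(field.speed) <= bound + 1e-9

    def test_featureless_frames_error(self, cal):
        a = MassFrame(np.zeros((64, 64)), 0.0, cal)
        b = MassFrame(np.zeros((64, 64)), 1.0, cal)
        from lving import CellMask

        with pytest.raises(InsufficientVectorsError):
            compute_velocity_field(a, b, CellMask(np.ones((64, 64), bool)))

    def test_nyquist_warning_on_fast_motion(self, textured_frame, cal):
        rolled = np.roll(textured_frame.density, 3, axis=1)  # 3 px/frame
        with pytest.warns(UserWarning, match="Nyquist"):
            compute_velocity_field(
                textured_frame, MassFrame(rolled, 1.0, cal), segment_cell(textured_frame)
            )


class TestMedianFilter:
    def test_uniform_field_unchanged(self):
        f = _uniform_field()
        out = median_filter_vectors(f, 3.0)
        assert np.array_equal(out.u, f.u) and np.array_equal(out.v, f.v)

    def test_spike_replaced_by_neighbour_median(self):
        f = _uniform_field()
        u = f.u.copy()
        u[2, 2] = 50.0
        spiked = dataclasses.replace(f, u=u)
        out = median_filter_vectors(spiked, 3.0)
        assert np.isclose(out.u[2, 2], 1.0)

    def test_small_grid_passthrough(self):
        f = _uniform_field(n=2)
        assert median_filter_vectors(f, 3.0) is f


class TestInterpolation:
    def test_node_value_at_node(self):
        f = _uniform_field(u=2.0, v=-1.0)
        out = interpolate_velocity(f, [(3.0, 3.0)])
        assert np.allclose(out, [[2.0, -1.0]])

    def test_uniform_everywhere(self):
        f = _uniform_field(u=0.5, v=0.25)
        pts = np.random.default_rng(1).uniform(1, 5, (20, 2))
        assert np.allclose(interpolate_velocity(f, pts), [0.5, 0.25])

    def test_bilinear_reproduces_linear_field(self):
        n = 5
        g = np.arange(n, dtype=float)
        xx, yy = np.meshgrid(g, g)
        f = VelocityField(grid_x=g, grid_y=g, u=xx.copy(), v=yy.copy(),
                          valid=np.ones((n, n), bool), dt=1.0)
        pts = np.random.default_rng(2).uniform(0, n - 1, (30, 2))
        out = interpolate_velocity(f, pts)
        assert np.allclose(out[:, 0], pts[:, 0], atol=1e-12)
        assert np.allclose(out[:, 1], pts[:, 1], atol=1e-12)

    def test_outside_points_clamped_to_edge(self):
        f = _uniform_field(u=1.0)
        out = interpolate_velocity(f, [(-10.0, 3.0), (100.0, 100.0)])
        assert np.allclose(out[:, 0], 1.0)


class TestAnchoredDisplacement:
    def test_recovers_cumulative_shift(self, textured_frame, cal):
        from scipy.ndimage import fourier_shift

        total = 2.3  # px, beyond a single-pair search at subpixel accuracy
        cur = MassFrame(
            np.real(np.fft.ifft2(fourier_shift(np.fft.fft2(textured_frame.density), (0.0, total)))),
            5.0,
            cal,
        )
        g = (np.arange(10, 22) * 8 + 16) * cal.pixel_size / 2  # nodes on the cell
        gx = gy = np.arange(8, 24) * cal.pixel_size * 4
        guess = np.full((len(gy), len(gx)), total * cal.pixel_size * 0.8)
        dx, dy, measured = anchored_displacement(
            textured_frame, cur, gx, gy, guess, np.zeros_like(guess)
        )
        sel = measured
        assert sel.sum() > 10
        assert np.allclose(dx[sel], total * cal.pixel_size, atol=0.03 * cal.pixel_size)
        assert np.allclose(dy[sel], 0.0, atol=0.03 * cal.pixel_size)
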