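"""Phase ingestion, background correction, conversion and segmentation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lving import (
    Calibration,
    CellMask,
    MassFrame,
    PhaseFrame,
    background_correct,
    phase_to_mass,
    segment_cell,
    total_mass,
)
from lving.mass_imaging import (
    EmptyBackgroundError,
    EmptySegmentationError,
    cytoplasm_mask,
    mass_to_phase,
    read_mask,
    read_opd_stack,
    write_mass_stack,
    write_opd_stack,
)


def _disk_opd(shape=(64, 64), center=(32, 32), radius=18, value=0.3):
    ii, jj = np.indices(shape)
    opd = np.zeros(shape)
    opd[(ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2] = value
    return opd


class TestCalibration:
    def test_defaults_and_pixel_area(self):
        c = Calibration(0.5, 1.0)
        assert c.refractive_increment == 0.18
        assert c.pixel_area == 0.25

    @pytest.mark.parametrize("bad", [dict(pixel_size=0), dict(frame_interval=-1),
                                     dict(refractive_increment=0.0)])
    def test_rejects_non_positive(self, bad):
        kwargs = dict(pixel_size=0.25, frame_interval=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            Calibration(**kwargs)


class TestBackgroundCorrect:
    def test_constant_offset_removed(self):
        opd = _disk_opd() + 0.05
        mask = CellMask(_disk_opd() > 0)
        out = background_correct(PhaseFrame(opd, 0.0), mask)
        assert np.allclose(out.opd, _disk_opd(), atol=1e-9)

    def test_idempotent_on_flat_background(self):
        opd = _disk_opd()
        mask = CellMask(opd > 0)
        once = background_correct(PhaseFrame(opd, 0.0), mask)
        twice = background_correct(once, mask)
        assert np.max(np.abs(twice.opd - once.opd)) < 1e-9

    def test_planar_ramp_removed(self):
        jj, ii = np.meshgrid(np.arange(64), np.arange(64))
        ramp = 1e-3 * jj - 5e-4 * ii + 0.02
        opd = _disk_opd() + ramp
        mask = CellMask(_disk_opd() > 0)
        out = background_correct(PhaseFrame(opd, 0.0), mask)
        bg = ~mask.mask
        assert np.sqrt(np.mean(out.opd[bg] ** 2)) < 1e-6

    def test_empty_background_errors(self):
        opd = np.ones((8, 8))
        with pytest.raises(EmptyBackgroundError):
            background_correct(PhaseFrame(opd, 0.0), CellMask(np.ones((8, 8), bool)))


class TestPhaseToMass:
    def test_zero_opd_gives_zero_density(self, cal):
        mf = phase_to_mass(PhaseFrame(np.zeros((8, 8)), 0.0), cal)
        assert np.all(mf.density == 0)

    def test_unit_conversion(self):
        cal = Calibration(pixel_size=1.0, frame_interval=1.0, refractive_increment=0.18)
        mf = phase_to_mass(PhaseFrame(np.full((4, 4), 0.18), 0.0), cal)
        assert np.allclose(mf.density, 1.0)
        assert np.isclose(total_mass(mf, CellMask(np.ones((4, 4), bool))), 16.0)

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(0.1, 10.0), alpha=st.floats(0.05, 1.0))
    def test_linear_and_invertible(self, scale, alpha):
        cal = Calibration(0.25, 1.0, refractive_increment=alpha)
        rng = np.random.default_rng(3)
        opd = rng.uniform(0, 0.5, (16, 16))
        one = phase_to_mass(PhaseFrame(opd, 0.0), cal)
        double = phase_to_mass(PhaseFrame(scale * opd, 0.0), cal)
        assert np.allclose(double.density, scale * one.density)
        assert np.allclose(mass_to_phase(one).opd, opd, atol=1e-14)


class TestSegmentCell:
    def test_disk_recovered_within_boundary_band(self, cal):
        ii, jj = np.indices((64, 64))
        truth = (ii - 32) ** 2 + (jj - 32) ** 2 <= 18**2
        mf = MassFrame(np.where(truth, 1.0, 0.0), 0.0, cal)
        mask = segment_cell(mf)
        from scipy import ndimage

        band_out = ndimage.binary_dilation(truth, iterations=2)
        band_in = ndimage.binary_erosion(truth, iterations=2)
        assert np.all(mask.mask[band_in])
        assert not np.any(mask.mask[~band_out])

    def test_all_zero_frame_errors(self, cal):
        with pytest.raises(EmptySegmentationError):
            segment_cell(MassFrame(np.zeros((32, 32)), 0.0, cal))

    def test_keeps_largest_of_two_disks(self, cal):
        ii, jj = np.indices((64, 64))
        big = (ii - 20) ** 2 + (jj - 20) ** 2 <= 12**2
        small = (ii - 48) ** 2 + (jj - 48) ** 2 <= 5**2
        mf = MassFrame(np.where(big | small, 1.0, 0.0), 0.0, cal)
        mask = segment_cell(mf)
        assert mask.mask[20, 20] and not mask.mask[48, 48]


class TestTotalMass:
    def test_hand_computed_value(self):
        cal = Calibration(pixel_size=0.5, frame_interval=1.0)
        density = np.zeros((10, 10))
        density[:5, :10] = 2.0  # 50 pixels at 2 pg/um^2
        mask = CellMask(density > 0)
        mf = MassFrame(density, 0.0, cal)
        assert np.isclose(total_mass(mf, mask), 2.0 * 50 * 0.25)

    def test_empty_mask_is_zero(self, textured_frame):
        assert total_mass(textured_frame, CellMask(np.zeros((128, 128), bool))) == 0.0

    def test_additive_over_disjoint_masks(self, textured_frame):
        left = np.zeros((128, 128), bool)
        left[:, :64] = True
        right = ~left
        full = CellMask(np.ones((128, 128), bool))
        assert np.isclose(
            total_mass(textured_frame, CellMask(left))
            + total_mass(textured_frame, CellMask(right)),
            total_mass(textured_frame, full),
        )


class TestMaskAlgebra:
    def test_cytoplasm_is_cell_minus_nucleus(self):
        cell = CellMask(np.ones((8, 8), bool), "cell")
        nuc = np.zeros((8, 8), bool)
        nuc[2:5, 2:5] = True
        cyto = cytoplasm_mask(cell, CellMask(nuc, "nucleus"))
        assert cyto.mask.sum() == 64 - 9
        assert not cyto.mask[3, 3]


class TestIO:
    def test_opd_stack_roundtrip(self, tmp_path, cal):
        frames = [PhaseFrame(np.random.default_rng(k).uniform(0, 0.4, (16, 16)), k * 1.0)
                  for k in range(3)]
        write_opd_stack(tmp_path / "m.tif", frames)
        (tmp_path / "m.json").write_text(json.dumps(
            {"pixel_size_um": 0.25, "frame_interval_min": 1.0}))
        back, cal2 = read_opd_stack(tmp_path / "m.tif", tmp_path / "m.json")
        assert len(back) == 3
        assert cal2.refractive_increment == 0.18
        assert np.allclose(back[1].opd, frames[1].opd, atol=1e-6)
        assert back[2].timestamp == 2.0

    def test_missing_sidecar_key_is_named(self, tmp_path):
        (tmp_path / "m.json").write_text(json.dumps({"pixel_size_um": 0.25}))
        with pytest.raises(KeyError, match="frame_interval_min"):
            from lving.mass_imaging import read_metadata_sidecar

            read_metadata_sidecar(tmp_path / "m.json")

    def test_mask_reading_nonzero_is_inside(self, tmp_path):
        import tifffile

        arr = np.zeros((8, 8), np.uint8)
        arr[2:6, 2:6] = 255
        tifffile.imwrite(tmp_path / "mask.tif", arr)
        mask = read_mask(tmp_path / "mask.tif")
        assert mask.mask.sum() == 16

    def test_mass_stack_written_as_float32(self, tmp_path, textured_frame):
        import tifffile

        write_mass_stack(tmp_path / "d.tif", [textured_frame])
        data = tifffile.imread(tmp_path / "d.tif")
        assert data.dtype == np.float32
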