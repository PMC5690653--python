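"""Diametry: axis estimation, reslicing, per-tubule and 2-D section diameters."""

import math

import numpy as np
import pytest

from tubulometry import (
    MeasureParams,
    estimate_common_axis,
    measure_section_diameters,
    measure_tubules,
    rasterize_cylinder,
    reslice_labels,
)
from tubulometry.volume_io import LabelVolume

SP = 5.0


def cylinder_labels(diameter_um, tilt_deg, grid=(96, 96, 96), length_um=250.0, azimuth_deg=0.0):
    th = math.radians(tilt_deg)
    az = math.radians(azimuth_deg)
    axis = (math.cos(th), math.sin(th) * math.cos(az), math.sin(th) * math.sin(az))
    center = tuple((n - 1) * SP / 2 for n in grid)
    mask = rasterize_cylinder(grid, SP, center, axis, diameter_um, length_um)
    return LabelVolume(mask.astype(np.uint32), (SP, SP, SP))


class TestEstimateCommonAxis:
    def test_axis_aligned_tubules(self):
        labels = cylinder_labels(30.0, 0.0)
        u = estimate_common_axis(labels)
        assert abs(u @ np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0, abs=1e-3)

    def test_jittered_phantom_axis_within_5_deg(self, small_phantom):
        from tubulometry import rasterize_truth_labels

        spec, _, _, truth = small_phantom
        labels = rasterize_truth_labels(truth, spec.grid_shape, spec.spacing_um)
        u = estimate_common_axis(labels)
        cos = abs(u @ np.array(spec.main_axis))
        assert math.degrees(math.acos(min(cos, 1.0))) <= 5.0

    def test_no_labels_raises(self):
        empty = LabelVolume(np.zeros((4, 4, 4), np.uint32), (SP,) * 3)
        with pytest.raises(ValueError):
            estimate_common_axis(empty)

    def test_isotropic_blob_flagged(self, caplog):
        labels = np.zeros((12, 12, 12), dtype=np.uint32)
        labels[4:9, 4:9, 4:9] = 1
        with caplog.at_level("WARNING"):
            u = estimate_common_axis(LabelVolume(labels, (SP,) * 3))
        assert np.linalg.norm(u) == pytest.approx(1.0)
        assert any("anisotropy" in r.message for r in caplog.records)


class TestResliceLabels:
    def test_native_axis_is_identity(self):
        labels = cylinder_labels(30.0, 0.0, grid=(40, 40, 40), length_um=120.0)
        out = reslice_labels(labels, (1.0, 0.0, 0.0))
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_90_degree_axis_is_permutation(self):
        rng = np.random.default_rng(0)
        arr = (rng.random((8, 9, 10)) < 0.2).astype(np.uint32)
        labels = LabelVolume(arr, (SP,) * 3)
        out = reslice_labels(labels, (0.0, 0.0, 1.0))  # slice normal along native x
        assert out.labels.shape[0] == 10
        for k in range(10):
            np.testing.assert_array_equal(out.labels[k], arr[:, :, k])

    def test_voxel_count_conserved_under_rotation(self):
        labels = cylinder_labels(40.0, 30.0)
        th = math.radians(30.0)
        out = reslice_labels(labels, (math.cos(th), math.sin(th), 0.0))
        n0 = np.count_nonzero(labels.labels)
        n1 = np.count_nonzero(out.labels)
        assert abs(n1 - n0) / n0 <= 0.02

    def test_no_new_label_values(self):
        labels = cylinder_labels(30.0, 20.0)
        out = reslice_labels(labels, (1.0, 0.2, 0.1) / np.linalg.norm([1.0, 0.2, 0.1]))
        assert set(np.unique(out.labels)) <= set(np.unique(labels.labels))


class TestMeasureTubules:
    def test_aligned_cylinder_within_one_voxel(self):
        labels = cylinder_labels(30.0, 0.0)
        meas, excl = measure_tubules(labels, estimate_common_axis(labels))
        assert len(meas) == 1 and not excl
        assert meas[0].summary_diameter_um == pytest.approx(30.0, abs=SP)

    def test_tilt_invariance_45_degrees(self):
        d0 = measure_tubules(
            cylinder_labels(30.0, 0.0), (1.0, 0.0, 0.0)
        )[0][0].summary_diameter_um
        labels45 = cylinder_labels(30.0, 45.0)
        d45 = measure_tubules(labels45, estimate_common_axis(labels45))[0][0].summary_diameter_um
        assert abs(d45 - 30.0) <= SP
        assert abs(d45 - d0) <= SP

    def test_monotone_in_true_diameter(self):
        est = []
        for d in (20.0, 30.0, 45.0, 60.0):
            labels = cylinder_labels(d, 10.0)
            est.append(measure_tubules(labels, estimate_common_axis(labels))[0][0].summary_diameter_um)
        assert est == sorted(est)

    def test_single_slice_label_excluded(self):
        labels = np.zeros((20, 20, 20), dtype=np.uint32)
        labels[10, 8:12, 8:12] = 1  # one-slice plate
        meas, excl = measure_tubules(
            LabelVolume(labels, (SP,) * 3), (1.0, 0.0, 0.0), params=MeasureParams(min_slices=3)
        )
        assert not meas
        assert excl[0]["reason"] in ("too_few_slices", "tilt")

    def test_steep_tubule_excluded_by_tilt_gate(self):
        labels = cylinder_labels(30.0, 0.0)
        # slice normal nearly perpendicular to the tubule axis
        meas, excl = measure_tubules(labels, (0.05, 0.9987, 0.0), params=MeasureParams())
        assert not meas
        assert excl and excl[0]["reason"] == "tilt"

    def test_median_robust_to_dropping_slices(self):
        labels = cylinder_labels(45.0, 15.0)
        meas, _ = measure_tubules(labels, estimate_common_axis(labels))
        diam = np.array(meas[0].slice_diameters_um)
        rng = np.random.default_rng(4)
        keep = rng.random(len(diam)) > 0.2
        assert abs(float(np.median(diam[keep])) - meas[0].summary_diameter_um) <= SP


class TestSectionDiameters:
    def test_disc_label(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 12.0**2).astype(np.int32)
        (tid, d), = measure_section_diameters(img, spacing_um=1.0)
        assert tid == 1
        assert d == pytest.approx(24.0, abs=1.0)

    def test_annulus_measured_by_outer_extent(self):
        yy, xx = np.mgrid[0:64, 0:64]
        r2 = (yy - 32) ** 2 + (xx - 32) ** 2
        img = ((r2 <= 20.0**2) & (r2 >= 10.0**2)).astype(np.int32)
        (_, d), = measure_section_diameters(img, spacing_um=1.0)
        assert d == pytest.approx(40.0, abs=1.0)

    def test_empty_image(self):
        assert measure_section_diameters(np.zeros((8, 8), np.int32)) == []

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            measure_section_diameters(np.zeros((4, 4, 4), np.int32))
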