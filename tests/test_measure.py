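"""Measurement tests: projection, segmentation, background masking,
banded cytoplasm sampling, per-cell means, ellipticity and linking."""

import math

import numpy as np
import pytest

from ktrquant.measure import (
    MaskedFrame,
    MeasurementError,
    NucleusROI,
    background_mask,
    band_roi,
    band_rois_for_frame,
    link_cells,
    max_project,
    measure_cell,
    measure_frame,
    measure_nuclear_3d,
    nucleus_ellipticity,
    segment_nuclei,
)
from ktrquant.stack import ImageStack
from ktrquant.synth import ktr_partition, render_scene

from conftest import single_cell_scene


def _stack_from_volume(vol: np.ndarray) -> ImageStack:
    """Wrap a (z, y, x) volume as a single-frame, single-channel stack."""
    return ImageStack(vol[None, None], 0.5, 60.0, channel_names=("c0",))


def _disk_roi(cy, cx, radius, shape, label=1) -> NucleusROI:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    pix = np.argwhere(mask)
    return NucleusROI(label=label, pixels=pix, centroid=(cy, cx), area_px=len(pix))


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        vol = rng.random((1, 8, 9))
        stack = _stack_from_volume(vol)
        assert np.array_equal(max_project(stack, 0, 0), vol[0])

    def test_uniform_brightest_plane(self):
        vol = np.ones((4, 6, 6))
        vol[2] = 5.0
        assert np.all(max_project(_stack_from_volume(vol), 0, 0) == 5.0)

    def test_matches_triple_loop_oracle(self, rng):
        vol = rng.random((4, 5, 6))
        out = max_project(_stack_from_volume(vol), 0, 0)
        for y in range(5):
            for x in range(6):
                expected = max(vol[z, y, x] for z in range(4))
                assert out[y, x] == expected

    def test_out_of_range(self):
        stack = _stack_from_volume(np.zeros((2, 4, 4)))
        with pytest.raises(IndexError):
            max_project(stack, 1, 0)
        with pytest.raises(IndexError):
            max_project(stack, 0, 5)


class TestSegmentNuclei:
    def test_blank_frame_no_rois(self):
        assert segment_nuclei(np.zeros((50, 50))) == []

    def test_three_disks_recovered(self):
        frame = np.full((100, 100), 5.0)
        centers = [(20, 20), (50, 70), (80, 30)]
        yy, xx = np.mgrid[0:100, 0:100]
        for cy, cx in centers:
            frame[(yy - cy) ** 2 + (xx - cx) ** 2 <= 36] = 100.0
        rois = segment_nuclei(frame, min_area_px=20)
        assert len(rois) == 3
        found = sorted(r.centroid for r in rois)
        for (fy, fx), (cy, cx) in zip(found, sorted(centers)):
            assert math.hypot(fy - cy, fx - cx) < 1.0

    def test_min_area_filter(self):
        yy, xx = np.mgrid[0:40, 0:40]
        small = np.full((40, 40), 5.0)
        small[(yy - 20) ** 2 + (xx - 20) ** 2 <= 1.7**2] = 100.0  # ~10 px disk
        assert segment_nuclei(small, min_area_px=30) == []

    def test_deterministic(self, rng):
        frame = rng.random((60, 60)) * 10
        frame[10:20, 10:20] += 100
        a = segment_nuclei(frame)
        b = segment_nuclei(frame)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert ra.label == rb.label and np.array_equal(ra.pixels, rb.pixels)


class TestBackgroundMask:
    def test_fixed_threshold(self):
        frame = np.zeros((20, 20))
        frame[5:10, 5:10] = 100.0
        masked = background_mask(frame, method="fixed", threshold_value=10.0)
        assert np.array_equal(masked.defined, frame >= 10.0)
        assert masked.threshold == 10.0

    def test_all_background(self):
        masked = background_mask(np.zeros((10, 10)))
        assert not masked.defined.any()

    def test_scene_coverage(self, noiseless_scene, noiseless_stack):
        frame = noiseless_stack.data[0, 0].max(axis=0)
        masked = background_mask(frame)
        cellmask = np.zeros(noiseless_scene.frame_shape, dtype=bool)
        for cell in noiseless_scene.cells:
            cellmask |= cell.cytoplasm_outer.mask(noiseless_scene.frame_shape)
        y0, y1, x0, x1 = noiseless_scene.da_region
        nonbg = cellmask.copy()
        nonbg[y0:y1, x0:x1] = True
        assert masked.defined[cellmask].mean() >= 0.99
        assert (~masked.defined[~nonbg]).mean() >= 0.95


class TestBandROI:
    def test_disjoint_from_parent(self):
        roi = _disk_roi(30, 30, 8, (60, 60))
        band = band_roi(roi, [roi], gap_px=1, width_px=4, frame_shape=(60, 60))
        parent = set(map(tuple, roi.pixels))
        assert parent.isdisjoint(set(map(tuple, band.pixels)))

    def test_disk_band_area_and_distance_oracle(self):
        # disk radius 10, gap 2, width 4: analytic ring area pi(16^2 - 12^2)
        roi = _disk_roi(50, 50, 10, (120, 120))
        band = band_roi(roi, [roi], gap_px=2, width_px=4, frame_shape=(120, 120))
        assert len(band.pixels) == pytest.approx(math.pi * (16**2 - 12**2), rel=0.10)
        # exhaustive pixel-distance enumeration
        nuc = roi.pixels
        expected = set()
        for y in range(120):
            for x in range(120):
                d = np.sqrt(((nuc - [y, x]) ** 2).sum(axis=1)).min()
                if 2 < d <= 6:
                    expected.add((y, x))
        assert set(map(tuple, band.pixels)) == expected

    def test_neighbor_nucleus_excluded(self):
        a = _disk_roi(30, 30, 5, (80, 80), label=1)
        b = _disk_roi(30, 45, 5, (80, 80), label=2)  # 5 px edge gap
        band_a = band_roi(a, [a, b], gap_px=2, width_px=4, frame_shape=(80, 80))
        bp = set(map(tuple, b.pixels))
        assert bp.isdisjoint(set(map(tuple, band_a.pixels)))

    def test_zero_width_error(self):
        roi = _disk_roi(10, 10, 3, (30, 30))
        with pytest.raises(ValueError):
            band_roi(roi, [roi], gap_px=1, width_px=0, frame_shape=(30, 30))

    def test_overlap_fraction_reported(self):
        a = _disk_roi(30, 30, 5, (80, 80), label=1)
        b = _disk_roi(30, 44, 5, (80, 80), label=2)
        bands = band_rois_for_frame([a, b], gap_px=1, width_px=4, frame_shape=(80, 80))
        assert bands[0].overlap_fraction > 0
        assert bands[0].overlap_fraction == pytest.approx(bands[1].overlap_fraction, rel=0.2)


class TestMeasureCell:
    def test_uniform_field(self):
        frame = np.full((60, 60), 50.0)
        masked = MaskedFrame(frame, np.ones_like(frame, bool))
        roi = _disk_roi(30, 30, 6, (60, 60))
        band = band_roi(roi, [roi], 1, 4, (60, 60))
        m = measure_cell(masked, frame, roi, band)
        assert m.nuclear_mean_ekc == 50.0
        assert m.cyto_mean_ekc == 50.0

    def test_piecewise_constant(self):
        frame = np.zeros((60, 60))
        roi = _disk_roi(30, 30, 6, (60, 60))
        band = band_roi(roi, [roi], 1, 4, (60, 60))
        frame[roi.pixels[:, 0], roi.pixels[:, 1]] = 80.0
        frame[band.pixels[:, 0], band.pixels[:, 1]] = 40.0
        masked = MaskedFrame(frame, frame > 0)
        m = measure_cell(masked, frame, roi, band)
        assert m.nuclear_mean_ekc == 80.0
        assert m.cyto_mean_ekc == 40.0

    def test_cyto_undefined_below_min_fraction(self):
        frame = np.full((60, 60), 50.0)
        roi = _disk_roi(30, 30, 6, (60, 60))
        band = band_roi(roi, [roi], 1, 4, (60, 60))
        defined = np.zeros_like(frame, bool)
        defined[roi.pixels[:, 0], roi.pixels[:, 1]] = True
        # only 10% of band pixels defined
        keep = band.pixels[: max(1, len(band.pixels) // 10)]
        defined[keep[:, 0], keep[:, 1]] = True
        m = measure_cell(MaskedFrame(frame, defined), frame, roi, band, min_defined_fraction=0.25)
        assert math.isnan(m.cyto_mean_ekc)
        assert m.defined_cyto_fraction < 0.25

    def test_undefined_nucleus_is_error(self):
        frame = np.full((40, 40), 50.0)
        roi = _disk_roi(20, 20, 5, (40, 40))
        band = band_roi(roi, [roi], 1, 4, (40, 40))
        with pytest.raises(MeasurementError):
            measure_cell(MaskedFrame(frame, np.zeros_like(frame, bool)), frame, roi, band)

    def test_noiseless_scene_ratio_recovery(self, noiseless_scene, noiseless_stack):
        truth = {}
        for cell in noiseless_scene.cells:
            truth[(round(cell.nucleus.cy), round(cell.nucleus.cx))] = cell
        for t in range(noiseless_stack.n_frames):
            _, cells = measure_frame(noiseless_stack, t)
            assert len(cells) == len(noiseless_scene.cells)
            for m in cells:
                key = min(
                    truth,
                    key=lambda k: (k[0] - m.centroid[0]) ** 2 + (k[1] - m.centroid[1]) ** 2,
                )
                expected = ktr_partition(truth[key].activity_curve[t], noiseless_scene.partition)
                assert m.nuclear_mean_ekc / m.cyto_mean_ekc == pytest.approx(expected, rel=0.05)


class TestMeasureNuclear3D:
    def test_single_z_equals_2d(self, rng):
        vol = rng.random((1, 10, 10)) * 100
        stack = _stack_from_volume(vol)
        vox = np.array([[0, 2, 3], [0, 4, 5], [0, 6, 7]])
        out = measure_nuclear_3d(stack, 0, vox)
        assert out["c0"] == pytest.approx(vol[0][[2, 4, 6], [3, 5, 7]].mean())

    def test_uniform_value(self):
        vol = np.full((3, 8, 8), 42.0)
        vox = np.array([[z, y, x] for z in range(3) for y in range(2, 5) for x in range(2, 5)])
        assert measure_nuclear_3d(_stack_from_volume(vol), 0, vox)["c0"] == 42.0

    def test_explicit_loop_oracle(self, rng):
        vol = rng.random((4, 6, 6))
        vox = np.array([[z, y, x] for z in range(4) for y in range(1, 4) for x in range(2, 5)])
        total = sum(vol[z, y, x] for z, y, x in vox)
        out = measure_nuclear_3d(_stack_from_volume(vol), 0, vox)
        assert out["c0"] == pytest.approx(total / len(vox))

    def test_empty_voxels_error(self):
        with pytest.raises(MeasurementError):
            measure_nuclear_3d(_stack_from_volume(np.zeros((2, 4, 4))), 0, np.empty((0, 3)))


class TestEllipticity:
    def test_disk_near_zero(self):
        roi = _disk_roi(40, 40, 15, (90, 90))
        assert nucleus_ellipticity(roi) < 0.05

    def test_ellipse_axis_ratio(self):
        yy, xx = np.mgrid[0:100, 0:100]
        mask = ((xx - 50) / 20.0) ** 2 + ((yy - 50) / 10.0) ** 2 <= 1.0
        pix = np.argwhere(mask)
        roi = NucleusROI(1, pix, (50, 50), len(pix))
        assert nucleus_ellipticity(roi) == pytest.approx(0.5, abs=0.05)

    def test_rotation_invariance(self):
        yy, xx = np.mgrid[0:100, 0:100]
        mask = ((xx - 50) / 18.0) ** 2 + ((yy - 50) / 9.0) ** 2 <= 1.0
        pix = np.argwhere(mask)
        e0 = nucleus_ellipticity(NucleusROI(1, pix, (50, 50), len(pix)))
        rot = np.column_stack([pix[:, 1], 99 - pix[:, 0]])  # 90 degrees
        e90 = nucleus_ellipticity(NucleusROI(1, rot, (50, 50), len(rot)))
        assert abs(e0 - e90) < 0.02

    def test_degenerate_collinear(self):
        pix = np.column_stack([np.full(10, 5), np.arange(10)])
        with pytest.raises(ValueError):
            nucleus_ellipticity(NucleusROI(1, pix, (5, 4.5), 10))


class TestLinkCells:
    def _rois_at(self, centers):
        return [
            _disk_roi(cy, cx, 4, (200, 200), label=i + 1) for i, (cy, cx) in enumerate(centers)
        ]

    def test_identity_mapping(self):
        rois = self._rois_at([(20, 20), (60, 60), (100, 40)])
        assert link_cells(rois, rois, max_disp_px=10) == {1: 1, 2: 2, 3: 3}

    def test_uniform_shift(self):
        a = self._rois_at([(20, 20), (60, 60), (100, 40)])
        b = self._rois_at([(23, 20), (63, 60), (103, 40)])
        assert link_cells(a, b, max_disp_px=10) == {1: 1, 2: 2, 3: 3}

    def test_large_displacement_rejected(self):
        a = self._rois_at([(20, 20), (60, 60)])
        b = self._rois_at([(20, 20), (110, 110)])
        assert link_cells(a, b, max_disp_px=10) == {1: 1}

    def test_invalid_max_disp(self):
        with pytest.raises(ValueError):
            link_cells([], [], max_disp_px=0)
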