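"""Generator tests: partition map, activity trajectories, rendering,
acquisition noise and reporter conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ktrquant.metrics import ActivityCurve
from ktrquant.stack import ImageStack
from ktrquant.synth import (
    ABLATED,
    ADJACENT,
    CONTROL,
    AcquisitionParams,
    Ellipse,
    GroundTruthScene,
    PartitionParams,
    SceneGenerationError,
    SyntheticCell,
    TrajectoryParams,
    apply_noise_and_bleach,
    activity_profile,
    ktr_partition,
    make_wound_scene,
    render_scene,
    simulate_activity_curves,
)

from conftest import single_cell_scene


class TestPartitionMap:
    @pytest.mark.parametrize(
        "E, expected",
        [
            (0.0, 2.0),  # nuclear-enriched endpoint
            (1.0, 0.5),  # nuclear-depleted endpoint
            (0.5, math.exp((math.log(2.0) + math.log(0.5)) / 2.0)),  # log-midpoint
        ],
    )
    def test_log_linear_values(self, E, expected):
        assert ktr_partition(E, PartitionParams(2.0, 0.5)) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing(self, e1, e2):
        if abs(e1 - e2) < 1e-9:  # below float resolution of the log map
            return
        lo, hi = sorted([e1, e2])
        assert ktr_partition(lo) > ktr_partition(hi)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ktr_partition(-0.1)
        with pytest.raises(ValueError):
            ktr_partition(1.2)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            PartitionParams(r_inactive=0.9, r_active=0.5)
        with pytest.raises(ValueError):
            PartitionParams(r_inactive=2.0, r_active=1.1)


class TestActivityCurves:
    def test_zero_noise_control_is_constant(self):
        times = np.arange(0.0, 21.0)
        params = TrajectoryParams(baseline=0.2, amplitude=0.0, noise_sd=0.0)
        curves = simulate_activity_curves({"control": (3, params)}, times, seed=0)
        for c in curves:
            assert np.allclose(c.values, 0.2)

    def test_adjacent_relaxes_to_baseline(self):
        # decay far shorter than the observation window: end within 1% of baseline
        times = np.arange(0.0, 200.0)
        params = TrajectoryParams(baseline=0.2, amplitude=0.5, tau_rise_min=2.0, tau_decay_min=5.0, noise_sd=0.0)
        (c,) = simulate_activity_curves({"adjacent": (1, params)}, times, seed=0)
        assert abs(c.values[-1] - 0.2) < 0.01 * 0.2 + 1e-9

    def test_ablated_rises_to_plateau(self):
        times = np.arange(0.0, 60.0)
        E = activity_profile(times, ABLATED)
        assert np.all(np.diff(E) >= -1e-12)
        assert E[-1] == pytest.approx(ABLATED.baseline + ABLATED.amplitude, rel=1e-3)

    def test_baseline_before_wound(self):
        times = np.arange(-10.0, 10.0)
        E = activity_profile(times, ABLATED)
        assert np.allclose(E[times <= 0], ABLATED.baseline)

    def test_position_grading(self):
        times = np.arange(2.0, 23.0)
        means = [activity_profile(times, ABLATED, position_index=p).mean() for p in range(1, 6)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_seed_determinism(self):
        times = np.arange(0.0, 21.0)
        design = {"control": (4, CONTROL), "ablated": (4, ABLATED)}
        a = simulate_activity_curves(design, times, seed=7)
        b = simulate_activity_curves(design, times, seed=7)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.values, cb.values)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            TrajectoryParams(tau_rise_min=-1.0)
        with pytest.raises(ValueError):
            TrajectoryParams(tau_decay_min=0.0)

    def test_values_stay_in_unit_interval(self):
        times = np.arange(0.0, 40.0)
        params = TrajectoryParams(baseline=0.9, amplitude=0.6, noise_sd=0.3)
        curves = simulate_activity_curves({"g": (10, params)}, times, seed=3)
        for c in curves:
            assert np.all((c.values >= 0) & (c.values <= 1))


class TestRenderScene:
    def test_single_cell_ratio_matches_partition(self):
        # direct pixel enumeration on the painted ellipses
        scene = single_cell_scene(E=0.0)
        stack = render_scene(scene)
        frame = stack.data[0, 0, 0]
        nuc = scene.cells[0].nucleus.mask(scene.frame_shape)
        cyto = scene.cells[0].cytoplasm_outer.mask(scene.frame_shape) & ~nuc
        ratio = frame[nuc].mean() / frame[cyto].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_empty_scene_is_background(self):
        acq = AcquisitionParams(background_level=7.0)
        scene = GroundTruthScene(cells=[], frame_shape=(40, 40), n_frames=2, acquisition=acq)
        stack = render_scene(scene)
        assert np.all(stack.data == 7.0)

    def test_activity_step_moves_signal(self):
        scene = single_cell_scene(E=0.0, n_frames=2, activity=[0.0, 1.0])
        stack = render_scene(scene)
        nuc = scene.cells[0].nucleus.mask(scene.frame_shape)
        cyto = scene.cells[0].cytoplasm_outer.mask(scene.frame_shape) & ~nuc
        assert stack.data[1, 0, 0][nuc].mean() < stack.data[0, 0, 0][nuc].mean()
        assert stack.data[1, 0, 0][cyto].mean() > stack.data[0, 0, 0][cyto].mean()

    def test_reporter_conservation(self, noiseless_scene, noiseless_stack):
        # shuttling redistributes signal between compartments, never creates it
        bg = noiseless_scene.acquisition.background_level
        for cell in noiseless_scene.cells:
            outer = cell.cytoplasm_outer.mask(noiseless_scene.frame_shape)
            totals = (noiseless_stack.data[:, 0, 0] - bg)[:, outer].sum(axis=1)
            assert totals.std() / totals.mean() < 0.01

    def test_h2b_only_in_nuclei(self, noiseless_scene, noiseless_stack):
        bg = noiseless_scene.acquisition.background_level
        all_nuc = np.zeros(noiseless_scene.frame_shape, dtype=bool)
        for cell in noiseless_scene.cells:
            all_nuc |= cell.nucleus.mask(noiseless_scene.frame_shape)
        h2b = noiseless_stack.data[0, 1, 0]
        assert np.all(h2b[~all_nuc] == bg)
        assert np.all(h2b[all_nuc] > bg)

    def test_overlapping_nuclei_rejected(self):
        cells = []
        for cid in (0, 1):
            cells.append(
                SyntheticCell(
                    cell_id=cid,
                    nucleus=Ellipse(40.0, 50.0 + cid * 2, 8.0, 6.0),
                    cytoplasm_outer=Ellipse(40.0, 50.0 + cid * 2, 16.0, 14.0),
                    h2b_intensity=400.0,
                    ekc_total=1e5,
                    activity_curve=[0.5],
                )
            )
        acq = AcquisitionParams()
        scene = GroundTruthScene(cells=cells, frame_shape=(80, 110), n_frames=1, acquisition=acq)
        with pytest.raises(SceneGenerationError):
            render_scene(scene)

    def test_nucleus_must_fit_in_cytoplasm(self):
        with pytest.raises(ValueError):
            SyntheticCell(
                cell_id=0,
                nucleus=Ellipse(40.0, 50.0, 10.0, 9.0),
                cytoplasm_outer=Ellipse(40.0, 50.0, 11.0, 10.0),
                h2b_intensity=400.0,
                ekc_total=1e5,
                activity_curve=[0.5],
            )


class TestNoiseAndBleach:
    def test_noise_free_identity(self):
        scene = single_cell_scene(E=0.3)
        stack = render_scene(scene)
        acq = AcquisitionParams(read_noise_sd=0.0, photon_scale=float("inf"))
        out = apply_noise_and_bleach(stack, acq, seed=0)
        assert np.array_equal(out.data, stack.data)

    def test_bleach_expectation(self):
        # constant input v: frame-10 mean should be v * 0.9^10 within MC error
        v = 200.0
        data = np.full((11, 1, 1, 64, 64), v)
        stack = ImageStack(data, 0.5, 60.0, channel_names=("c0",))
        acq = AcquisitionParams(
            bleach_rate_per_frame={0: 0.1}, read_noise_sd=1.0, photon_scale=1.0
        )
        out = apply_noise_and_bleach(stack, acq, seed=5)
        expected = v * 0.9**10
        n_px = 64 * 64
        se = math.sqrt(expected / 1.0 + 1.0) / math.sqrt(n_px)
        assert abs(out.data[10].mean() - expected) < 5 * se

    def test_seeded_determinism(self):
        scene = single_cell_scene(E=0.4, n_frames=3, activity=[0.4, 0.4, 0.4])
        stack = render_scene(scene)
        acq = AcquisitionParams(read_noise_sd=2.0, photon_scale=1.0, bleach_rate_per_frame={0: 0.05})
        a = apply_noise_and_bleach(stack, acq, seed=42)
        b = apply_noise_and_bleach(stack, acq, seed=42)
        assert np.array_equal(a.data, b.data)
        c = apply_noise_and_bleach(stack, acq, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_output_nonnegative(self):
        scene = single_cell_scene(E=0.5)
        stack = render_scene(scene)
        acq = AcquisitionParams(read_noise_sd=50.0, photon_scale=0.1)
        out = apply_noise_and_bleach(stack, acq, seed=1)
        assert np.all(out.data >= 0)

    def test_invalid_bleach_rate(self):
        with pytest.raises(ValueError):
            AcquisitionParams(bleach_rate_per_frame={0: 1.0})


class TestWoundScene:
    def test_groups_and_positions(self):
        scene = make_wound_scene(n_control=2, n_ablated=3, n_adjacent=2, seed=0)
        groups = {}
        for c in scene.cells:
            groups.setdefault(c.group_label, []).append(c.position_index)
        assert sorted(groups["ablated"]) == [1, 2, 3]
        assert sorted(groups["adjacent"]) == [1, 2]
        assert groups["control"] == [0, 0]

    def test_da_region_disjoint_from_nuclei(self):
        scene = make_wound_scene(seed=4)
        y0, y1, x0, x1 = scene.da_region
        for cell in scene.cells:
            mask = cell.nucleus.mask(scene.frame_shape)
            assert not mask[y0:y1, x0:x1].any()

    def test_activity_classes(self):
        scene = make_wound_scene(activity_noise=False, seed=0)
        t = scene.times_min()
        early = (t >= 2) & (t <= 22)
        late = t >= 120
        by_group = {}
        for c in scene.cells:
            by_group.setdefault(c.group_label, []).append(c.activity_curve)
        ctrl = np.mean([a[early].mean() for a in by_group["control"]])
        abl = np.mean([a[early].mean() for a in by_group["ablated"]])
        adj = np.mean([a[early].mean() for a in by_group["adjacent"]])
        assert abl > adj > ctrl
        abl_late = np.mean([a[late].mean() for a in by_group["ablated"]])
        adj_late = np.mean([a[late].mean() for a in by_group["adjacent"]])
        assert abl_late > ctrl + 0.2
        assert abs(adj_late - ctrl) < 0.02
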