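import numpy as np
import pytest

from ktrquant.synth import (
    AcquisitionParams,
    GroundTruthScene,
    Ellipse,
    PartitionParams,
    SyntheticCell,
    make_wound_scene,
    render_scene,
)


def single_cell_scene(E: float, n_frames: int = 1, activity=None) -> GroundTruthScene:
    """One isolated cell on a clean background, noise-free acquisition."""
    if activity is None:
        activity = np.full(n_frames, E)
    cell = SyntheticCell(
        cell_id=0,
        nucleus=Ellipse(40.0, 50.0, 8.0, 6.0, 0.3),
        cytoplasm_outer=Ellipse(40.0, 50.0, 16.0, 14.0, 0.3),
        h2b_intensity=400.0,
        ekc_total=1.0e5,
        activity_curve=np.asarray(activity, dtype=float),
    )
    acq = AcquisitionParams(background_level=0.0, read_noise_sd=0.0, photon_scale=float("inf"))
    return GroundTruthScene(
        cells=[cell], frame_shape=(80, 100), n_frames=n_frames, acquisition=acq
    )


@pytest.fixture(scope="session")
def noiseless_scene():
    """A small noise-free wound scene shared across measurement tests."""
    scene = make_wound_scene(
        n_control=2,
        n_ablated=2,
        n_adjacent=2,
        frame_times_min=np.arange(-2.0, 6.0),
        activity_noise=False,
        seed=11,
    )
    return scene


@pytest.fixture(scope="session")
def noiseless_stack(noiseless_scene):
    return render_scene(noiseless_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
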