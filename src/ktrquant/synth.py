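"""Synthetic two-channel KTR microscopy with known ground truth.

The generator emulates the imaging situation the measurement pipeline is
built for: endothelial nuclei (nuclear marker channel) arranged along
vessel-like segments, each cell expressing a fixed total amount of a
kinase-translocation reporter whose nuclear/cytoplasmic partition is set
by a hidden per-cell activity E(t) in [0, 1]. Scenes are rendered
noiselessly first; photobleaching and Poisson-Gaussian camera noise are
applied as a separate, seeded step so every intermediate is testable.

The hidden activity trajectories come in three classes mirroring a
vessel-wounding experiment: flat controls, a rapid sustained rise in
wounded vessels, and a transient rise-and-decay in adjacent vessels,
with amplitude and onset graded by a cell's rank from the wound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import ActivityCurve
from .rng import derived_rng
from .stack import ImageStack

__all__ = [
    "PartitionParams",
    "AcquisitionParams",
    "TrajectoryParams",
    "Ellipse",
    "SyntheticCell",
    "GroundTruthScene",
    "ktr_partition",
    "activity_profile",
    "simulate_activity_curves",
    "make_wound_scene",
    "render_scene",
    "apply_noise_and_bleach",
    "ground_truth_table",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class PartitionParams:
    """Map from kinase activity E to nuclear/cytoplasmic reporter ratio.

    ``r_inactive`` (> 1) is the concentration ratio with the kinase off
    (reporter nuclear-enriched); ``r_active`` (< 1) with the kinase fully
    on (reporter nuclear-depleted). The default map interpolates
    log-linearly between the two, symmetric in log space.
    """

    r_inactive: float = 2.0
    r_active: float = 0.5
    shape: str = "log-linear"

    def __post_init__(self) -> None:
        if not (self.r_active < 1.0 < self.r_inactive):
            raise ValueError("require r_active < 1 < r_inactive")
        if not (np.isfinite(self.r_active) and np.isfinite(self.r_inactive)):
            raise ValueError("partition ratios must be finite")
        if self.r_active <= 0:
            raise ValueError("r_active must be positive")
        if self.shape != "log-linear":
            raise ValueError(f"unknown partition map shape {self.shape!r}")


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera / acquisition model parameters.

    ``bleach_rate_per_frame`` maps channel index to the fractional
    intensity loss per frame (0 = no bleaching); ``photon_scale`` is the
    gain converting intensity units to expected photon counts for the
    Poisson component (``inf`` disables shot noise).
    """

    pixel_size_um: float = 0.5
    frame_interval_s: float = 60.0
    n_z: int = 3
    background_level: float = 5.0
    read_noise_sd: float = 2.0
    photon_scale: float = 1.0
    bleach_rate_per_frame: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0 and self.frame_interval_s > 0):
            raise ValueError("pixel size and frame interval must be positive")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read noise must be nonnegative")
        if not (self.photon_scale > 0):
            raise ValueError("photon_scale must be positive (inf allowed)")
        for ch, rate in self.bleach_rate_per_frame.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"bleach rate for channel {ch} must be in [0, 1)")

    def bleach_rate(self, channel: int) -> float:
        return self.bleach_rate_per_frame.get(channel, 0.0)


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of the wound-response activity family.

    E(t) = baseline for t < 0 and
    E(t) = baseline + amplitude * (1 - exp(-t/tau_rise))
                    * exp(-max(0, t - t_on)/tau_decay)   for t >= 0,

    clipped to [0, 1]. ``tau_decay = inf`` gives a sustained plateau
    (wounded-vessel class); a finite decay gives the transient
    rise-and-relax of adjacent vessels. Times in minutes; the wound is
    at t = 0.
    """

    baseline: float = 0.2
    amplitude: float = 0.0
    tau_rise_min: float = 3.0
    tau_decay_min: float = math.inf
    t_on_min: float = 0.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline <= 1.0):
            raise ValueError("baseline must be in [0, 1]")
        if self.tau_rise_min <= 0 or self.tau_decay_min <= 0:
            raise ValueError("rise and decay time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


#: default trajectory classes of the wound scenario
CONTROL = TrajectoryParams(amplitude=0.0)
ABLATED = TrajectoryParams(amplitude=0.6, tau_decay_min=math.inf)
ADJACENT = TrajectoryParams(amplitude=0.45, tau_decay_min=25.0)

DEFAULT_TRAJECTORIES: dict[str, TrajectoryParams] = {
    "control": CONTROL,
    "ablated": ABLATED,
    "adjacent": ADJACENT,
}

#: graded wound response by cell rank from the wound (1 = closest):
#: each rank step reduces amplitude by this fraction and delays onset.
AMPLITUDE_DECAY_PER_RANK = 0.12
ONSET_DELAY_PER_RANK_MIN = 1.5


# ---------------------------------------------------------------------------
# partition map and activity trajectories


def ktr_partition(E, params: PartitionParams = PartitionParams()):
    """Nuclear/cytoplasmic reporter concentration ratio at activity E.

    Log-linear in E: ln r(E) = (1-E) ln r_inactive + E ln r_active.
    Strictly decreasing, r(0) = r_inactive, r(1) = r_active. Accepts
    scalars or arrays; E outside [0, 1] is a domain error.
    """
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr < 0) or np.any(E_arr > 1) or not np.all(np.isfinite(E_arr)):
        raise ValueError("activity E must lie in [0, 1]")
    log_r = (1.0 - E_arr) * math.log(params.r_inactive) + E_arr * math.log(params.r_active)
    r = np.exp(log_r)
    return float(r) if np.isscalar(E) else r


def activity_profile(times_min: np.ndarray, params: TrajectoryParams, position_index: int = 0) -> np.ndarray:
    """Noise-free activity E(t) for one cell.

    ``position_index`` >= 1 grades the response by rank from the wound:
    amplitude shrinks by ``AMPLITUDE_DECAY_PER_RANK`` per rank step and
    onset is delayed by ``ONSET_DELAY_PER_RANK_MIN`` minutes per step.
    """
    t = np.asarray(times_min, dtype=float)
    amp = params.amplitude
    delay = 0.0
    if position_index >= 1:
        amp = amp * max(0.0, 1.0 - AMPLITUDE_DECAY_PER_RANK * (position_index - 1))
        delay = ONSET_DELAY_PER_RANK_MIN * (position_index - 1)
    ts = t - delay
    rise = np.where(ts > 0, 1.0 - np.exp(-np.maximum(ts, 0.0) / params.tau_rise_min), 0.0)
    if math.isinf(params.tau_decay_min):
        decay = np.ones_like(ts)
    else:
        decay = np.exp(-np.maximum(0.0, ts - params.t_on_min) / params.tau_decay_min)
    E = params.baseline + amp * rise * decay
    return np.clip(E, 0.0, 1.0)


def simulate_activity_curves(
    design: dict[str, tuple[int, TrajectoryParams]],
    times_min: np.ndarray,
    seed: int = 0,
    grade_by_position: bool = False,
) -> list[ActivityCurve]:
    """Draw per-cell activity curves for a named group design.

    ``design`` maps group label -> (n_cells, trajectory params). Noise is
    iid Gaussian per timepoint (sd from the params), clipped to [0, 1];
    identical seeds give identical output. With ``grade_by_position``
    the cells of each non-control group get position indices 1..n and
    the graded response of :func:`activity_profile`.
    """
    times_min = np.asarray(times_min, dtype=float)
    if times_min.ndim != 1 or np.any(np.diff(times_min) <= 0):
        raise ValueError("timepoints must be 1D and strictly increasing")
    curves: list[ActivityCurve] = []
    cell_id = 0
    for group in sorted(design):
        n, params = design[group]
        if n < 1:
            raise ValueError(f"group {group!r} must have >= 1 cell")
        rng = derived_rng(seed, "activity", group)
        for i in range(n):
            pos = (i + 1) if (grade_by_position and group != "control") else 0
            E = activity_profile(times_min, params, position_index=pos)
            if params.noise_sd > 0:
                E = np.clip(E + rng.normal(0.0, params.noise_sd, size=E.shape), 0.0, 1.0)
            curves.append(
                ActivityCurve(
                    times=times_min.copy(),
                    values=E,
                    cell_id=cell_id,
                    group_label=group,
                    position_index=pos,
                )
            )
            cell_id += 1
    return curves


# ---------------------------------------------------------------------------
# scene geometry


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-then-rotated ellipse: center (cy, cx), semi-axes a >= b,
    orientation theta (radians, major axis from +x)."""

    cy: float
    cx: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("require semi-axes a >= b > 0")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean raster of the ellipse interior on a (y, x) grid with
        pixel centers at integer coordinates."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        dy = yy - self.cy
        dx = xx - self.cx
        ct, st = math.cos(self.theta), math.sin(self.theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0

    def bounds_within(self, shape: tuple[int, int], margin: float = 0.0) -> bool:
        r = self.a + margin
        return (
            self.cy - r >= 0
            and self.cx - r >= 0
            and self.cy + r <= shape[0] - 1
            and self.cx + r <= shape[1] - 1
        )


@dataclass
class SyntheticCell:
    """One simulated cell: geometry, marker brightness, total reporter,
    hidden activity trajectory and experimental-group annotation."""

    cell_id: int
    nucleus: Ellipse
    cytoplasm_outer: Ellipse
    h2b_intensity: float
    ekc_total: float
    activity_curve: np.ndarray
    group_label: str = "control"
    position_index: int = 0

    def __post_init__(self) -> None:
        self.activity_curve = np.asarray(self.activity_curve, dtype=float)
        if np.any(self.activity_curve < 0) or np.any(self.activity_curve > 1):
            raise ValueError("activity curve must lie in [0, 1]")
        if self.h2b_intensity <= 0 or self.ekc_total <= 0:
            raise ValueError("intensities must be positive")
        n, c = self.nucleus, self.cytoplasm_outer
        # nucleus strictly inside the outer ellipse: require the nucleus'
        # circumscribing circle inside the outer ellipse's inscribed circle
        dist = math.hypot(n.cy - c.cy, n.cx - c.cx)
        if dist + n.a >= c.b:
            raise ValueError("nucleus must lie strictly inside the cytoplasm envelope")


@dataclass
class GroundTruthScene:
    """Hidden state of a synthetic experiment.

    ``da_region`` is a rectangle (y0, y1, x0, x1), half-open, standing in
    for the dorsal aorta used as a normalization reference; it must be
    disjoint from every nucleus. ``frame_times_min`` places each frame
    on the experiment clock (wound at t = 0).
    """

    cells: list[SyntheticCell]
    frame_shape: tuple[int, int]
    n_frames: int
    acquisition: AcquisitionParams
    partition: PartitionParams = PartitionParams()
    da_region: tuple[int, int, int, int] | None = None
    da_ekc_intensity: float = 150.0
    frame_times_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for cell in self.cells:
            if len(cell.activity_curve) != self.n_frames:
                raise ValueError("every activity curve must have n_frames entries")
            if not cell.cytoplasm_outer.bounds_within(self.frame_shape):
                raise ValueError(f"cell {cell.cell_id} geometry exceeds frame bounds")
        if self.frame_times_min is not None:
            self.frame_times_min = np.asarray(self.frame_times_min, dtype=float)
            if self.frame_times_min.shape != (self.n_frames,):
                raise ValueError("frame_times_min must have one entry per frame")
        if self.da_region is not None:
            y0, y1, x0, x1 = self.da_region
            if not (0 <= y0 < y1 <= self.frame_shape[0] and 0 <= x0 < x1 <= self.frame_shape[1]):
                raise ValueError("da_region must be a nonempty in-bounds rectangle")
            for cell in self.cells:
                n = cell.nucleus
                if y0 - n.a < n.cy < y1 + n.a and x0 - n.a < n.cx < x1 + n.a:
                    raise ValueError("da_region overlaps a nucleus")

    def times_min(self) -> np.ndarray:
        if self.frame_times_min is not None:
            return self.frame_times_min
        return np.arange(self.n_frames) * self.acquisition.frame_interval_s / 60.0


class SceneGenerationError(RuntimeError):
    """Raised when non-overlapping cell placement cannot be achieved."""


def _place_cells_along_segment(
    n: int,
    x_center: float,
    y_range: tuple[float, float],
    min_spacing: float,
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> list[tuple[float, float]]:
    """Place n centers along a vertical vessel-like segment: evenly spaced
    slots with random jitter, rejection-sampled until the minimum pairwise
    spacing holds; error after ``max_attempts``."""
    y0, y1 = y_range
    if n == 1:
        base = np.array([(y0 + y1) / 2.0])
    else:
        base = np.linspace(y0, y1, n)
        if base[1] - base[0] <= min_spacing:
            raise SceneGenerationError(
                f"segment too short for {n} cells at spacing {min_spacing:.1f}px"
            )
    slack = 0.0 if n == 1 else (base[1] - base[0] - min_spacing) / 2.0
    for _ in range(max_attempts):
        ys = np.clip(base + rng.uniform(-slack, slack, size=n), y0, y1)
        xs = x_center + rng.uniform(-2.0, 2.0, size=n)
        pts = np.column_stack([ys, xs])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() > min_spacing:
            return [tuple(p) for p in pts]
    raise SceneGenerationError(
        f"could not place {n} non-overlapping cells after {max_attempts} attempts"
    )


def make_wound_scene(
    n_control: int = 3,
    n_ablated: int = 5,
    n_adjacent: int = 3,
    frame_times_min: np.ndarray | None = None,
    acquisition: AcquisitionParams | None = None,
    partition: PartitionParams = PartitionParams(),
    trajectories: dict[str, TrajectoryParams] | None = None,
    frame_shape: tuple[int, int] = (180, 260),
    nucleus_axes: tuple[float, float] = (6.0, 4.0),
    cyto_margin_px: float = 7.0,
    h2b_intensity: float = 400.0,
    ekc_total: float = 1.0e5,
    activity_noise: bool = True,
    seed: int = 0,
) -> GroundTruthScene:
    """Build the standard vessel-wounding scene.

    Three vertical vessel-like segments carry the control, wounded
    ("ablated") and adjacent cell groups; wounded/adjacent cells get
    position indices 1..n by rank from the wound (top of the segment).
    The default imaging schedule covers a pre-wound epoch (-20..-1 min),
    the early post-wound window (2..22 min) and a late epoch (~3 h).
    """
    if acquisition is None:
        acquisition = AcquisitionParams(seed=seed)
    if trajectories is None:
        trajectories = DEFAULT_TRAJECTORIES
    if frame_times_min is None:
        frame_times_min = np.concatenate(
            [np.arange(-20.0, 0.0), np.arange(2.0, 23.0), np.arange(180.0, 185.0)]
        )
    frame_times_min = np.asarray(frame_times_min, dtype=float)
    n_frames = frame_times_min.size

    rng = derived_rng(seed, "scene")
    a_nuc, b_nuc = nucleus_axes
    outer_a = a_nuc + cyto_margin_px
    min_spacing = 2 * outer_a + 2.0
    margin = outer_a + 3.0
    y_range = (margin, frame_shape[0] - margin)

    groups = [("control", n_control), ("ablated", n_ablated), ("adjacent", n_adjacent)]
    # vessel x positions: spread across the right 2/3 of the frame, the
    # left strip is reserved for the dorsal-aorta reference rectangle
    xs = np.linspace(frame_shape[1] * 0.42, frame_shape[1] * 0.9, len(groups))

    cells: list[SyntheticCell] = []
    cid = 0
    for (group, n), x_center in zip(groups, xs):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        params = trajectories[group]
        if not activity_noise:
            params = replace(params, noise_sd=0.0)
        centers = _place_cells_along_segment(n, x_center, y_range, min_spacing, rng)
        centers.sort()  # rank from the wound = top of the segment
        grng = derived_rng(seed, "activity", group)
        for rank, (cy, cx) in enumerate(centers, start=1):
            pos = rank if group != "control" else 0
            E = activity_profile(frame_times_min, params, position_index=pos)
            if params.noise_sd > 0:
                E = np.clip(E + grng.normal(0.0, params.noise_sd, size=E.shape), 0.0, 1.0)
            theta = rng.uniform(0, math.pi)
            cells.append(
                SyntheticCell(
                    cell_id=cid,
                    nucleus=Ellipse(cy, cx, a_nuc, b_nuc, theta),
                    cytoplasm_outer=Ellipse(cy, cx, outer_a, b_nuc + cyto_margin_px, theta),
                    h2b_intensity=h2b_intensity,
                    ekc_total=ekc_total,
                    activity_curve=E,
                    group_label=group,
                    position_index=pos,
                )
            )
            cid += 1

    da = (
        int(frame_shape[0] * 0.25),
        int(frame_shape[0] * 0.75),
        4,
        int(frame_shape[1] * 0.22),
    )
    return GroundTruthScene(
        cells=cells,
        frame_shape=frame_shape,
        n_frames=n_frames,
        acquisition=acquisition,
        partition=partition,
        da_region=da,
        frame_times_min=frame_times_min,
    )


# ---------------------------------------------------------------------------
# rendering and acquisition noise


def render_scene(scene: GroundTruthScene) -> ImageStack:
    """Render a noiseless, bleach-free two-channel stack from ground truth.

    Per cell and frame the nuclear and cytoplasmic reporter pixel
    concentrations satisfy c_nuc / c_cyt = ktr_partition(E(t)) exactly on
    the rasterized masks, and c_nuc * A_nuc + c_cyt * A_cyt = ekc_total,
    so total reporter per cell is conserved while activity redistributes
    it. The nuclear-marker channel is nonzero only inside nuclei. The
    constant camera background is added to both channels.
    """
    acq = scene.acquisition
    ny, nx = scene.frame_shape
    data = np.zeros((scene.n_frames, 2, acq.n_z, ny, nx), dtype=np.float64)

    # cache masks once per cell; geometry is static over the movie
    cell_masks = []
    all_nuc = np.zeros((ny, nx), dtype=bool)
    for cell in scene.cells:
        nuc = cell.nucleus.mask((ny, nx))
        outer = cell.cytoplasm_outer.mask((ny, nx))
        if np.any(nuc & all_nuc):
            raise SceneGenerationError(f"nucleus of cell {cell.cell_id} overlaps another nucleus")
        all_nuc |= nuc
        cyto = outer & ~nuc
        a_n, a_c = int(nuc.sum()), int(cyto.sum())
        if a_n == 0 or a_c == 0:
            raise SceneGenerationError(f"cell {cell.cell_id} rasterizes to an empty region")
        cell_masks.append((cell, nuc, cyto, a_n, a_c))

    ekc = np.zeros((scene.n_frames, ny, nx))
    h2b = np.zeros((scene.n_frames, ny, nx))
    for cell, nuc, cyto, a_n, a_c in cell_masks:
        r = ktr_partition(cell.activity_curve, scene.partition)  # (n_frames,)
        c_cyt = cell.ekc_total / (r * a_n + a_c)
        c_nuc = r * c_cyt
        ekc[:, nuc] += c_nuc[:, None]
        ekc[:, cyto] += c_cyt[:, None]
        h2b[:, nuc] += cell.h2b_intensity

    if scene.da_region is not None:
        y0, y1, x0, x1 = scene.da_region
        ekc[:, y0:y1, x0:x1] += scene.da_ekc_intensity

    data[:, 0] = ekc[:, None, :, :] + acq.background_level
    data[:, 1] = h2b[:, None, :, :] + acq.background_level
    return ImageStack(
        data=data,
        pixel_size_um=acq.pixel_size_um,
        frame_interval_s=acq.frame_interval_s,
        channel_names=("EKC", "H2B-mCherry"),
        frame_times_min=scene.frame_times_min,
    )


def apply_noise_and_bleach(stack: ImageStack, acq: AcquisitionParams, seed: int | None = None) -> ImageStack:
    """Apply per-channel exponential photobleaching and Poisson-Gaussian
    camera noise.

    The expected intensity of channel c at frame t is scaled by
    (1 - bleach_rate[c])**t. Shot noise: Poisson on the photon_scale-
    scaled signal (skipped when photon_scale is inf); read noise:
    additive Gaussian. Output is clipped at zero. Deterministic for a
    fixed (stack, params, seed).
    """
    if seed is None:
        seed = acq.seed
    rng = derived_rng(seed, "noise")
    out = stack.data.copy()
    t_idx = np.arange(stack.n_frames, dtype=float)
    for c in range(stack.n_channels):
        rate = acq.bleach_rate(c)
        if rate > 0:
            factors = (1.0 - rate) ** t_idx
            out[:, c] *= factors[:, None, None, None]
    if math.isfinite(acq.photon_scale):
        out = rng.poisson(out * acq.photon_scale).astype(np.float64) / acq.photon_scale
    if acq.read_noise_sd > 0:
        out = out + rng.normal(0.0, acq.read_noise_sd, size=out.shape)
    np.clip(out, 0.0, None, out=out)
    return ImageStack(
        data=out,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        channel_names=tuple(stack.channel_names),
        frame_times_min=None if stack.frame_times_min is None else stack.frame_times_min.copy(),
    )


# ---------------------------------------------------------------------------
# ground-truth export


def ground_truth_table(scene: GroundTruthScene) -> pd.DataFrame:
    """One row per (cell, frame): hidden activity, true partition ratio and
    true pixel concentrations, plus geometry and group annotation."""
    ny, nx = scene.frame_shape
    times = scene.times_min()
    rows = []
    for cell in scene.cells:
        nuc = cell.nucleus.mask((ny, nx))
        cyto = cell.cytoplasm_outer.mask((ny, nx)) & ~nuc
        a_n, a_c = int(nuc.sum()), int(cyto.sum())
        r = ktr_partition(cell.activity_curve, scene.partition)
        c_cyt = cell.ekc_total / (r * a_n + a_c)
        for t in range(scene.n_frames):
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "frame": t,
                    "time_min": times[t],
                    "group": cell.group_label,
                    "position_index": cell.position_index,
                    "E": cell.activity_curve[t],
                    "nc_ratio_true": r[t],
                    "nuclear_conc": r[t] * c_cyt[t],
                    "cyto_conc": c_cyt[t],
                    "centroid_y": cell.nucleus.cy,
                    "centroid_x": cell.nucleus.cx,
                    "nucleus_a": cell.nucleus.a,
                    "nucleus_b": cell.nucleus.b,
                    "theta": cell.nucleus.theta,
                }
            )
    return pd.DataFrame(rows)
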