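"""Nucleus / banded-cytoplasm reporter quantification.

Implements the projected-2D measurement procedure used for KTR imaging:
maximum-intensity z-projection, nuclear segmentation by thresholding the
nuclear-marker channel, conversion of non-cell background pixels to
undefined (NaN), banded cytoplasm sampling around each nucleus, and
per-cell mean intensities — plus 3D nuclear means, a moment-based
nucleus ellipticity, and greedy frame-to-frame identity linking.

All quantification operates on raw intensities; bleach correction (see
:mod:`ktrquant.bleach`) is for display/QC only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure as skmeasure

from .stack import ImageStack

__all__ = [
    "MaskedFrame",
    "NucleusROI",
    "BandROI",
    "CellMeasurement",
    "max_project",
    "segment_nuclei",
    "background_mask",
    "band_roi",
    "band_rois_for_frame",
    "measure_cell",
    "measure_frame",
    "measure_stack",
    "measure_nuclear_3d",
    "nucleus_ellipticity",
    "link_cells",
]

logger = logging.getLogger(__name__)

#: below this fraction of defined band pixels the cytoplasmic mean (and
#: hence the nuclear/cytoplasmic ratio) is reported as undefined
DEFAULT_MIN_DEFINED_FRACTION = 0.25
DEFAULT_GAP_PX = 1
DEFAULT_WIDTH_PX = 4


class MeasurementError(RuntimeError):
    pass


@dataclass
class MaskedFrame:
    """A 2D frame with an explicit defined/undefined pixel mask.

    Statistics must be computed over defined pixels only; the threshold
    that produced the mask is kept for provenance.
    """

    values: np.ndarray
    defined: np.ndarray
    threshold: float = math.nan
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != self.defined.shape or self.values.ndim != 2:
            raise ValueError("values and defined must be matching 2D arrays")

    def mean_over(self, pixels: np.ndarray) -> tuple[float, float]:
        """(mean over defined pixels of the set, defined fraction).

        Raises if the pixel set is empty; returns (nan, 0.0) when no
        pixel of a nonempty set is defined.
        """
        if len(pixels) == 0:
            raise MeasurementError("mean over empty pixel set")
        ys, xs = pixels[:, 0], pixels[:, 1]
        ok = self.defined[ys, xs]
        frac = float(ok.mean())
        if not ok.any():
            return math.nan, 0.0
        return float(self.values[ys, xs][ok].mean()), frac


@dataclass
class NucleusROI:
    """A segmented nucleus: labelled 4-connected pixel set."""

    label: int
    pixels: np.ndarray  # (n, 2) int array of (y, x)
    centroid: tuple[float, float]
    area_px: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or len(self.pixels) == 0:
            raise ValueError("pixels must be a nonempty (n, 2) array")
        if self.label <= 0:
            raise ValueError("labels are positive integers")


@dataclass
class BandROI:
    """Banded cytoplasm sampling region around a nucleus.

    Pixels at Euclidean distance in (gap_px, gap_px + width_px] from the
    parent nucleus' pixel set, excluding every segmented nucleus.
    ``overlap_fraction`` is the fraction of band pixels shared with any
    other cell's band (bands are not arbitrated).
    """

    parent_label: int
    pixels: np.ndarray
    gap_px: int
    width_px: int
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)


@dataclass
class CellMeasurement:
    """Per-cell, per-frame intensity summary."""

    cell_id: int
    frame_index: int
    nuclear_mean_ekc: float
    nuclear_mean_h2b: float
    cyto_mean_ekc: float  # NaN when undefined
    defined_cyto_fraction: float
    area_px: int = 0
    centroid: tuple[float, float] = (math.nan, math.nan)
    ellipticity: float = math.nan
    band_overlap_fraction: float = 0.0
    nuclear_mean_ekc_3d: float = math.nan


# ---------------------------------------------------------------------------
# projection and segmentation


def max_project(stack: ImageStack, channel: int, frame: int) -> np.ndarray:
    """Maximum-intensity z-projection of one channel of one frame."""
    if not (0 <= frame < stack.n_frames and 0 <= channel < stack.n_channels):
        raise IndexError("frame or channel out of range")
    return stack.data[frame, channel].max(axis=0)


def _threshold(frame: np.ndarray, method: str, value: float | None) -> float:
    if method == "fixed":
        if value is None:
            raise ValueError("fixed threshold requires a value")
        return float(value)
    if frame.max() == frame.min():
        raise ValueError("unthresholdable uniform frame")
    if method == "otsu":
        return float(filters.threshold_otsu(frame))
    if method == "triangle":
        return float(filters.threshold_triangle(frame))
    raise ValueError(f"unknown threshold method {method!r}")


def segment_nuclei(
    h2b_frame: np.ndarray,
    min_area_px: int = 20,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
) -> list[NucleusROI]:
    """Threshold the nuclear-marker frame and label connected components.

    Components below ``min_area_px`` are discarded. 4-connectivity;
    labels are assigned in scan order, so the result is deterministic.
    A uniform (unthresholdable) frame yields an empty list with a
    warning.
    """
    h2b_frame = np.asarray(h2b_frame, dtype=float)
    try:
        thr = _threshold(h2b_frame, threshold_method, threshold_value)
    except ValueError as err:
        if "uniform" in str(err):
            logger.warning("segment_nuclei: %s; returning no ROIs", err)
            return []
        raise
    mask = h2b_frame > thr
    labels = skmeasure.label(mask, connectivity=1)
    rois = []
    for prop in skmeasure.regionprops(labels):
        if prop.area < min_area_px:
            continue
        rois.append(
            NucleusROI(
                label=int(prop.label),
                pixels=np.asarray(prop.coords),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_px=int(prop.area),
            )
        )
    return rois


def background_mask(
    ekc_frame: np.ndarray,
    method: str = "triangle",
    threshold_value: float | None = None,
) -> MaskedFrame:
    """Mark non-cell background pixels of the reporter frame undefined.

    Pixels strictly below the computed threshold become undefined, the
    software analogue of converting background to NaN in a 32-bit image.
    """
    ekc_frame = np.asarray(ekc_frame, dtype=float)
    try:
        thr = _threshold(ekc_frame, method, threshold_value)
    except ValueError as err:
        if "uniform" in str(err):
            # uniform frame: everything is background by convention
            return MaskedFrame(ekc_frame, np.zeros_like(ekc_frame, bool), math.nan, method)
        raise
    return MaskedFrame(ekc_frame, ekc_frame >= thr, thr, method)


# ---------------------------------------------------------------------------
# banded cytoplasm sampling


def band_roi(
    nucleus: NucleusROI,
    all_nuclei: list[NucleusROI],
    gap_px: int = DEFAULT_GAP_PX,
    width_px: int = DEFAULT_WIDTH_PX,
    frame_shape: tuple[int, int] | None = None,
) -> BandROI:
    """Banded selection of adjacent cytoplasm around one nucleus.

    Selects pixels whose Euclidean distance to the nucleus pixel set
    lies in (gap_px, gap_px + width_px], clipped to the frame and with
    all segmented nuclei removed. An empty band is allowed (flagged by
    an empty pixel array); cytoplasm statistics are then undefined.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    if gap_px < 0:
        raise ValueError("gap_px must be >= 0")
    if frame_shape is None:
        raise ValueError("frame_shape is required")
    nuc_mask = np.zeros(frame_shape, dtype=bool)
    nuc_mask[nucleus.pixels[:, 0], nucleus.pixels[:, 1]] = True
    dist = ndimage.distance_transform_edt(~nuc_mask)
    band = (dist > gap_px) & (dist <= gap_px + width_px)
    for other in all_nuclei:
        band[other.pixels[:, 0], other.pixels[:, 1]] = False
    band[nucleus.pixels[:, 0], nucleus.pixels[:, 1]] = False
    pixels = np.argwhere(band)
    if len(pixels) == 0:
        logger.warning("empty cytoplasm band for nucleus %d", nucleus.label)
    return BandROI(parent_label=nucleus.label, pixels=pixels, gap_px=gap_px, width_px=width_px)


def band_rois_for_frame(
    nuclei: list[NucleusROI],
    gap_px: int = DEFAULT_GAP_PX,
    width_px: int = DEFAULT_WIDTH_PX,
    frame_shape: tuple[int, int] | None = None,
) -> list[BandROI]:
    """Bands for every nucleus of a frame, with per-band overlap fractions.

    Overlapping band pixels are retained in every band (no arbitration);
    the overlap fraction is reported so downstream users can filter.
    """
    bands = [band_roi(n, nuclei, gap_px, width_px, frame_shape) for n in nuclei]
    if frame_shape is not None and len(bands) > 1:
        counts = np.zeros(frame_shape, dtype=np.int32)
        for b in bands:
            if len(b.pixels):
                counts[b.pixels[:, 0], b.pixels[:, 1]] += 1
        for b in bands:
            if len(b.pixels):
                shared = counts[b.pixels[:, 0], b.pixels[:, 1]] > 1
                b.overlap_fraction = float(shared.mean())
    return bands


# ---------------------------------------------------------------------------
# per-cell measurement


def measure_cell(
    masked_ekc: MaskedFrame,
    h2b_frame: np.ndarray,
    nucleus: NucleusROI,
    band: BandROI,
    min_defined_fraction: float = DEFAULT_MIN_DEFINED_FRACTION,
    frame_index: int = 0,
) -> CellMeasurement:
    """Mean reporter intensity over the nucleus and its cytoplasm band.

    Means are over defined pixels only. The cytoplasmic mean is reported
    undefined (NaN) when fewer than ``min_defined_fraction`` of the band
    pixels are defined — below that the nuclear/cytoplasmic ratio is not
    trustworthy. A nucleus with no defined pixel is a measurement error.
    """
    h2b_frame = np.asarray(h2b_frame, dtype=float)
    nuc_mean, nuc_frac = masked_ekc.mean_over(nucleus.pixels)
    if not np.isfinite(nuc_mean):
        raise MeasurementError(
            f"nucleus {nucleus.label} entirely undefined in the reporter frame"
        )
    del nuc_frac
    if len(band.pixels):
        cyto_mean, cyto_frac = masked_ekc.mean_over(band.pixels)
    else:
        cyto_mean, cyto_frac = math.nan, 0.0
    if cyto_frac < min_defined_fraction:
        cyto_mean = math.nan
    h2b_mean = float(h2b_frame[nucleus.pixels[:, 0], nucleus.pixels[:, 1]].mean())
    try:
        ell = nucleus_ellipticity(nucleus)
    except ValueError:
        ell = math.nan
    return CellMeasurement(
        cell_id=nucleus.label,
        frame_index=frame_index,
        nuclear_mean_ekc=nuc_mean,
        nuclear_mean_h2b=h2b_mean,
        cyto_mean_ekc=cyto_mean,
        defined_cyto_fraction=cyto_frac,
        area_px=nucleus.area_px,
        centroid=nucleus.centroid,
        ellipticity=ell,
        band_overlap_fraction=band.overlap_fraction,
    )


def measure_nuclear_3d(stack: ImageStack, frame: int, nucleus_voxels: np.ndarray) -> dict[str, float]:
    """Plain mean intensity per channel over a 3D nuclear voxel set.

    ``nucleus_voxels`` is an (n, 3) integer array of (z, y, x).
    """
    voxels = np.asarray(nucleus_voxels, dtype=int)
    if voxels.ndim != 2 or voxels.shape[1] != 3 or len(voxels) == 0:
        raise MeasurementError("nucleus voxel set must be nonempty (n, 3)")
    nz, ny, nx = stack.data.shape[2:]
    if (
        voxels.min() < 0
        or voxels[:, 0].max() >= nz
        or voxels[:, 1].max() >= ny
        or voxels[:, 2].max() >= nx
    ):
        raise MeasurementError("voxel set out of bounds")
    out = {}
    for c, name in enumerate(stack.channel_names):
        vals = stack.data[frame, c, voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        out[name] = float(vals.mean())
    return out


def nucleus_ellipticity(roi: NucleusROI) -> float:
    """Moment-based ellipticity e = 1 - minor/major axis of the
    moment-equivalent ellipse; 0 for a disk, rotation invariant."""
    if roi.area_px < 5:
        raise ValueError("ellipticity requires area >= 5 px")
    pts = roi.pixels.astype(float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 1e-12:
        raise ValueError("degenerate (collinear) pixel set")
    minor, major = math.sqrt(evals[0]), math.sqrt(evals[1])
    return 1.0 - minor / major


def link_cells(
    rois_a: list[NucleusROI],
    rois_b: list[NucleusROI],
    max_disp_px: float,
) -> dict[int, int]:
    """Greedy nearest-centroid identity linking between consecutive frames.

    Candidate pairs are taken in order of (distance, label_a, label_b);
    each ROI is matched at most once and pairs farther than
    ``max_disp_px`` are rejected (the cell starts or ends a track).
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be positive")
    pairs = []
    for ra in rois_a:
        for rb in rois_b:
            d = math.hypot(ra.centroid[0] - rb.centroid[0], ra.centroid[1] - rb.centroid[1])
            if d <= max_disp_px:
                pairs.append((d, ra.label, rb.label))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    mapping: dict[int, int] = {}
    for d, la, lb in pairs:
        if la in used_a or lb in used_b:
            continue
        mapping[la] = lb
        used_a.add(la)
        used_b.add(lb)
    return mapping


# ---------------------------------------------------------------------------
# frame- and stack-level drivers


def measure_frame(
    stack: ImageStack,
    frame: int,
    min_area_px: int = 20,
    threshold_method: str = "otsu",
    background_method: str = "triangle",
    gap_px: int = DEFAULT_GAP_PX,
    width_px: int = DEFAULT_WIDTH_PX,
    min_defined_fraction: float = DEFAULT_MIN_DEFINED_FRACTION,
) -> tuple[list[NucleusROI], list[CellMeasurement]]:
    """Segment and measure every cell of one frame (projected pipeline)."""
    h2b = max_project(stack, 1, frame)
    ekc = max_project(stack, 0, frame)
    nuclei = segment_nuclei(h2b, min_area_px=min_area_px, threshold_method=threshold_method)
    masked = background_mask(ekc, method=background_method)
    bands = band_rois_for_frame(nuclei, gap_px, width_px, stack.frame_shape)
    cells = [
        measure_cell(masked, h2b, n, b, min_defined_fraction, frame_index=frame)
        for n, b in zip(nuclei, bands)
    ]
    return nuclei, cells


def measure_stack(
    stack: ImageStack,
    max_disp_px: float = 10.0,
    **frame_kwargs,
) -> pd.DataFrame:
    """Measure every frame and link identities into tracks.

    Returns a tidy table with one row per (track, frame). ``cell_id`` is
    the track id, stable across frames via greedy nearest-centroid
    linking.
    """
    times = stack.times_min()
    prev_rois: list[NucleusROI] = []
    label_to_track: dict[int, int] = {}
    next_track = 0
    rows = []
    for t in range(stack.n_frames):
        rois, cells = measure_frame(stack, t, **frame_kwargs)
        if t == 0 or not prev_rois:
            mapping = {}
        else:
            mapping = link_cells(prev_rois, rois, max_disp_px)
        inv = {lb: la for la, lb in mapping.items()}
        new_label_to_track: dict[int, int] = {}
        for roi in rois:
            if roi.label in inv and inv[roi.label] in label_to_track:
                new_label_to_track[roi.label] = label_to_track[inv[roi.label]]
            else:
                new_label_to_track[roi.label] = next_track
                next_track += 1
        for roi, cm in zip(rois, cells):
            rows.append(
                {
                    "cell_id": new_label_to_track[roi.label],
                    "frame": t,
                    "time_min": times[t],
                    "nuclear_mean_ekc": cm.nuclear_mean_ekc,
                    "nuclear_mean_h2b": cm.nuclear_mean_h2b,
                    "cyto_mean_ekc": cm.cyto_mean_ekc,
                    "defined_cyto_fraction": cm.defined_cyto_fraction,
                    "area_px": cm.area_px,
                    "ellipticity": cm.ellipticity,
                    "band_overlap_fraction": cm.band_overlap_fraction,
                    "centroid_y": cm.centroid[0],
                    "centroid_x": cm.centroid[1],
                }
            )
        prev_rois = rois
        label_to_track = new_label_to_track
    return pd.DataFrame(rows)
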