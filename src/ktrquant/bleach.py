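"""Histogram-matching bleach correction for time-lapse display/QC.

Photobleaching progressively dims a movie; matching every frame's
intensity histogram to a reference frame (by a monotone quantile
mapping) restores comparable brightness for display. Quantification
stays on raw data — corrected stacks are for visual inspection and QC
only, and the pipeline refuses to quantify them unless explicitly told
to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import ImageStack

__all__ = ["histogram_match", "ecdf_distance", "correct_stack", "BleachCorrectionReport"]

DEFAULT_N_BINS = 256


def _binned_cdf(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    hist, _ = np.histogram(values, bins=edges)
    cdf = np.cumsum(hist).astype(float)
    return cdf / cdf[-1]


def _binned_quantiles(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """(representative value, CDF) per nonempty histogram bin.

    The representative is the mean of the values that fell in the bin,
    so a point mass (e.g. uniform background) is represented exactly
    rather than by its bin center; the CDF over nonempty bins is
    strictly increasing, giving a well-defined inverse.
    """
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.array([lo]), np.array([1.0])
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    nz = counts > 0
    means = sums[nz] / counts[nz]
    cdf = np.cumsum(counts[nz]) / values.size
    return means, cdf


def histogram_match(frame: np.ndarray, reference: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Match ``frame``'s intensity distribution to ``reference``'s.

    Quantile mapping on an ``n_bins`` shared-range grid: each pixel value
    is sent through the frame's interpolated CDF and back through the
    reference's interpolated inverse CDF. The mapping is monotone
    nondecreasing, so pixel rank order is preserved; a frame identical
    to the reference comes back unchanged up to the bin resolution.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.size == 0 or reference.size == 0:
        raise ValueError("empty frame")
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    if np.any(frame < 0) or np.any(reference < 0):
        raise ValueError("frames must be nonnegative")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    # each distribution is binned over its own range, so resolution does
    # not degrade as a frame bleaches toward a narrower dynamic range
    src_vals, src_cdf = _binned_quantiles(frame.ravel(), n_bins)
    ref_vals, ref_cdf = _binned_quantiles(reference.ravel(), n_bins)
    # pixel value -> source quantile -> reference value at that quantile
    q = np.interp(frame.ravel(), src_vals, src_cdf)
    vals = np.interp(q, ref_cdf, ref_vals)
    return vals.reshape(frame.shape)


def ecdf_distance(frame: np.ndarray, reference: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> float:
    """Sup-norm distance between the binned ECDFs of two frames on a
    shared intensity grid (a KS-type distance used for the QC report)."""
    frame = np.asarray(frame, dtype=float).ravel()
    reference = np.asarray(reference, dtype=float).ravel()
    lo = min(frame.min(), reference.min())
    hi = max(frame.max(), reference.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    return float(np.max(np.abs(_binned_cdf(frame, edges) - _binned_cdf(reference, edges))))


@dataclass
class BleachCorrectionReport:
    """Per-frame QC of a correction run.

    By construction post-correction ECDF distance to the reference never
    exceeds the pre-correction distance: frames where matching would not
    improve the distance are left unchanged.
    """

    reference_frame: int
    n_bins: int
    channel: int
    frame: list[int] = field(default_factory=list)
    pre_mean: list[float] = field(default_factory=list)
    post_mean: list[float] = field(default_factory=list)
    pre_ecdf_distance: list[float] = field(default_factory=list)
    post_ecdf_distance: list[float] = field(default_factory=list)
    corrected: list[bool] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "pre_mean": self.pre_mean,
                "post_mean": self.post_mean,
                "pre_ecdf_distance": self.pre_ecdf_distance,
                "post_ecdf_distance": self.post_ecdf_distance,
                "corrected": self.corrected,
            }
        )


def correct_stack(
    stack: ImageStack,
    channel: int = 0,
    reference_frame_index: int = 0,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[ImageStack, BleachCorrectionReport]:
    """Histogram-match every frame of one channel to a reference frame.

    Matching operates on the full (z, y, x) volume of the channel. A
    frame is replaced only when matching strictly reduces its ECDF
    distance to the reference, which guarantees the report invariant
    post <= pre on every frame.
    """
    if not (0 <= reference_frame_index < stack.n_frames):
        raise IndexError("reference frame out of range")
    if not (0 <= channel < stack.n_channels):
        raise IndexError("channel out of range")
    out = stack.copy()
    ref = stack.data[reference_frame_index, channel]
    report = BleachCorrectionReport(
        reference_frame=reference_frame_index, n_bins=n_bins, channel=channel
    )
    for t in range(stack.n_frames):
        frame = stack.data[t, channel]
        pre_d = ecdf_distance(frame, ref, n_bins)
        matched = histogram_match(frame, ref, n_bins)
        post_d = ecdf_distance(matched, ref, n_bins)
        take = post_d < pre_d
        if take:
            out.data[t, channel] = matched
        report.frame.append(t)
        report.pre_mean.append(float(frame.mean()))
        report.post_mean.append(float(out.data[t, channel].mean()))
        report.pre_ecdf_distance.append(pre_d)
        report.post_ecdf_distance.append(min(post_d, pre_d) if not take else post_d)
        report.corrected.append(bool(take))
    return out, report
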