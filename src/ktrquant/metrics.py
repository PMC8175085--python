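"""Activity metrics and normalization schemes for KTR measurements.

Per-cell reporter intensities only become comparable across cells,
larvae and imaging sessions after normalization. This module implements
the ratios and reference normalizations used for endothelial Erk
reporter quantification:

* nuclear/cytoplasm reporter ratio (the core KTR readout; values > 1
  mean nuclear-enriched reporter, i.e. kinase-inactive),
* nuclear reporter / nuclear-marker ratio,
* normalization by a large reference structure (the dorsal aorta) to
  cancel acquisition gain, with post-/pre-wound ratios on top,
* normalization to a reference timepoint of a trace,
* tip/stalk cell ratios, per-minute binning, Ca2+-indicator (GCaMP)
  tissue normalization, and percentage vessel-regrowth.

Undefined measurements propagate as NaN; no metric silently converts an
undefined input to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivityCurve",
    "NormalizationContext",
    "nuc_cyt_ratio",
    "ekc_h2b_ratio",
    "da_normalize",
    "post_pre_ratio",
    "normalize_to_reference_time",
    "tip_stalk_ratio",
    "bin_by_minute",
    "gcamp_normalize",
    "regen_percent",
]


@dataclass
class ActivityCurve:
    """A per-cell time series of an activity metric.

    ``values`` may contain NaN where the metric was undefined at a
    timepoint (e.g. cytoplasmic sampling failed). ``position_index``
    ranks the cell by distance from a wound (1 = closest); 0 means
    not applicable.
    """

    times: np.ndarray
    values: np.ndarray
    cell_id: int = 0
    group_label: str = ""
    position_index: int = 0
    time_unit: str = "min"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1D and equal length")
        if self.times.size == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.time_unit not in ("s", "min"):
            raise ValueError("time_unit must be 's' or 'min'")

    def times_min(self) -> np.ndarray:
        return self.times / 60.0 if self.time_unit == "s" else self.times

    def with_values(self, values: np.ndarray) -> "ActivityCurve":
        return ActivityCurve(
            times=self.times.copy(),
            values=np.asarray(values, dtype=float),
            cell_id=self.cell_id,
            group_label=self.group_label,
            position_index=self.position_index,
            time_unit=self.time_unit,
        )


@dataclass
class NormalizationContext:
    """Reference intensities used by the normalization schemes.

    ``da_mean_pre`` / ``da_mean_post`` are mean reporter intensities of
    the dorsal-aorta reference region before and after wounding;
    ``tissue_mean_gcamp`` is the mean Ca2+-indicator intensity of
    uninjured tissue in the same larva.
    """

    da_mean_pre: float = math.nan
    da_mean_post: float = math.nan
    reference_time: float = math.nan
    tissue_mean_gcamp: float = math.nan

    def da_mean(self, phase: str) -> float:
        if phase == "pre":
            return self.da_mean_pre
        if phase == "post":
            return self.da_mean_post
        raise ValueError("phase must be 'pre' or 'post'")


def nuc_cyt_ratio(nuclear_mean, cyto_mean: float | None = None) -> float:
    """Nuclear / cytoplasmic reporter intensity ratio.

    Accepts either a :class:`~ktrquant.measure.CellMeasurement` or the
    two means directly. Values above 1 indicate nuclear enrichment of
    the reporter (kinase inactive); below 1, cytoplasmic enrichment
    (kinase active). Returns NaN when the cytoplasmic mean is undefined.
    """
    if cyto_mean is None and hasattr(nuclear_mean, "nuclear_mean_ekc"):
        m = nuclear_mean
        nuclear_mean, cyto_mean = m.nuclear_mean_ekc, m.cyto_mean_ekc
    if cyto_mean is None or not np.isfinite(cyto_mean):
        return math.nan
    if cyto_mean <= 0:
        raise ValueError("cytoplasmic mean must be positive when defined")
    return float(nuclear_mean) / float(cyto_mean)


def ekc_h2b_ratio(nuclear_mean_ekc, nuclear_mean_h2b: float | None = None) -> float:
    """Nuclear reporter / nuclear-marker intensity ratio.

    Accepts either a :class:`~ktrquant.measure.CellMeasurement` or the
    two nuclear means directly.
    """
    if nuclear_mean_h2b is None and hasattr(nuclear_mean_ekc, "nuclear_mean_ekc"):
        m = nuclear_mean_ekc
        nuclear_mean_ekc, nuclear_mean_h2b = m.nuclear_mean_ekc, m.nuclear_mean_h2b
    if not (nuclear_mean_h2b > 0):
        raise ValueError("nuclear marker mean must be positive")
    if not np.isfinite(nuclear_mean_ekc):
        return math.nan
    return float(nuclear_mean_ekc) / float(nuclear_mean_h2b)


def da_normalize(nuclear_mean: float, ctx: NormalizationContext, phase: str) -> float:
    """Normalize a nuclear reporter mean by the dorsal-aorta reference mean
    of the matching acquisition phase ('pre' or 'post' wounding)."""
    da = ctx.da_mean(phase)
    if not (da > 0):
        raise ValueError(f"DA reference mean for phase {phase!r} must be positive")
    if not np.isfinite(nuclear_mean):
        return math.nan
    return float(nuclear_mean) / float(da)


def post_pre_ratio(norm_post: float, norm_pre: float) -> float:
    """Ratio of post- to pre-wounding normalized nuclear intensity.

    1.0 = unchanged; < 1 = nuclear reporter depletion, i.e. kinase
    activation.
    """
    if not np.isfinite(norm_pre) or not np.isfinite(norm_post):
        return math.nan
    if norm_pre <= 0:
        raise ValueError("pre-ablation normalized intensity must be positive")
    return float(norm_post) / float(norm_pre)


def normalize_to_reference_time(curve: ActivityCurve, t_ref: float) -> ActivityCurve:
    """Divide a curve by its value at ``t_ref`` (must be on the grid and
    defined, nonzero); the output equals 1 there."""
    idx = np.nonzero(np.isclose(curve.times, t_ref))[0]
    if idx.size == 0:
        raise ValueError(f"reference time {t_ref} not on the curve's time grid")
    ref = curve.values[idx[0]]
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("value at the reference time is undefined or zero")
    return curve.with_values(curve.values / ref)


def tip_stalk_ratio(tip: ActivityCurve, stalk: ActivityCurve) -> ActivityCurve:
    """Element-wise tip/stalk intensity ratio on the shared time grid."""
    common = np.intersect1d(tip.times, stalk.times)
    if common.size == 0:
        raise ValueError("curves share no timepoints")
    ti = np.searchsorted(tip.times, common)
    si = np.searchsorted(stalk.times, common)
    denom = stalk.values[si]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom != 0, tip.values[ti] / denom, np.nan)
    return ActivityCurve(
        times=common,
        values=ratio,
        cell_id=tip.cell_id,
        group_label=tip.group_label,
        position_index=tip.position_index,
        time_unit=tip.time_unit,
    )


def bin_by_minute(curve: ActivityCurve) -> ActivityCurve:
    """Average samples within half-open one-minute bins [k, k+1).

    Bin time is the bin start k (in minutes). NaN samples are skipped;
    bins with no defined sample are dropped.
    """
    t_min = curve.times_min()
    bins = np.floor(t_min).astype(int)
    out_t, out_v = [], []
    for k in np.unique(bins):
        vals = curve.values[bins == k]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out_t.append(float(k))
            out_v.append(float(vals.mean()))
    if not out_t:
        raise ValueError("no defined samples to bin")
    return ActivityCurve(
        times=np.array(out_t),
        values=np.array(out_v),
        cell_id=curve.cell_id,
        group_label=curve.group_label,
        position_index=curve.position_index,
        time_unit="min",
    )


def gcamp_normalize(isv_mean: float, ctx: NormalizationContext) -> float:
    """Normalize a vessel-ROI Ca2+-indicator mean to the uninjured-tissue
    mean of the same larva (baseline ~ 1)."""
    if not (ctx.tissue_mean_gcamp > 0):
        raise ValueError("tissue reference mean must be positive")
    if not np.isfinite(isv_mean):
        return math.nan
    return float(isv_mean) / float(ctx.tissue_mean_gcamp)


def regen_percent(actual_height: float, prospective_height: float, cap: bool = False) -> float:
    """Percentage vessel regrowth: 100 * actual / prospective height.

    Uncapped by default; ``cap=True`` clips at 100%.
    """
    if not (prospective_height > 0):
        raise ValueError("prospective height must be positive")
    if actual_height < 0:
        raise ValueError("actual height must be nonnegative")
    pct = 100.0 * float(actual_height) / float(prospective_height)
    return min(pct, 100.0) if cap else pct
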