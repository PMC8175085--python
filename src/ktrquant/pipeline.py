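"""End-to-end wound-experiment orchestration.

Runs simulate -> render -> measure -> metrics -> stats as one
reproducible experiment: a synthetic vessel-wounding scene is rendered
and acquired, every cell is segmented, tracked and measured, nuclear
intensities are normalized against the dorsal-aorta reference region,
post-/pre-wound ratios and reference-time-normalized curves are
computed, and the two curve-comparison tests are applied. Every output
CSV carries a provenance header (tool version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bleach import correct_stack
from .measure import measure_stack
from .metrics import ActivityCurve, NormalizationContext, da_normalize, normalize_to_reference_time, post_pre_ratio
from .stack import ImageStack, read_stack, write_stack
from .stats import GroupedCurves, ks_critical_d, ks_decision, permutation_mean_curve_test
from .synth import (
    AcquisitionParams,
    PartitionParams,
    apply_noise_and_bleach,
    ground_truth_table,
    make_wound_scene,
    render_scene,
)

__all__ = ["RunConfig", "PipelineError", "run_wound_experiment", "make_fixtures"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a wound-experiment run.

    Defaults are the package's standard desk-scale study conditions:
    pre-wound frames at -20..-1 min, the early post-wound window at
    2..22 min, a late epoch near 3 h, and the default synthetic groups.
    """

    out_dir: str = "ktrquant_run"
    seed: int = 0
    # scene
    n_control: int = 3
    n_ablated: int = 5
    n_adjacent: int = 3
    effect_scale: float = 1.0  # multiplies response amplitudes (0 = null scenario)
    # measurement
    threshold_method: str = "otsu"
    background_method: str = "triangle"
    min_area_px: int = 20
    gap_px: int = 1
    band_width_px: int = 4
    min_defined_fraction: float = 0.25
    max_disp_px: float = 10.0
    # normalization
    reference_time_min: float = 2.0
    # stats
    alpha_ks: float = 0.001
    alpha_default: float = 0.05
    n_permutations: int = 999
    # flags
    quantify_corrected: bool = False
    registration: str = "none"  # hook only; no algorithm implemented

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        # identifies the experiment, not where it was written
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _provenance_header(config: RunConfig) -> str:
    return (
        f"# ktrquant {__version__}\n"
        f"# config_hash={config.config_hash()}\n"
        f"# seed={config.seed}\n"
    )


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    buf = io.StringIO()
    buf.write(_provenance_header(config))
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def _match_tracks_to_truth(measured: pd.DataFrame, truth: pd.DataFrame) -> dict[int, int]:
    """Map measured track ids to ground-truth cell ids by frame-0 centroid
    proximity (the synthetic annotation route: no wound auto-detection)."""
    m0 = measured[measured["frame"] == measured["frame"].min()]
    t0 = truth[truth["frame"] == 0].drop_duplicates("cell_id")
    mapping = {}
    for _, row in m0.iterrows():
        d = np.hypot(t0["centroid_y"] - row["centroid_y"], t0["centroid_x"] - row["centroid_x"])
        j = int(np.argmin(d.to_numpy()))
        if d.to_numpy()[j] <= 5.0:
            mapping[int(row["cell_id"])] = int(t0.iloc[j]["cell_id"])
    return mapping


def run_wound_experiment(config: RunConfig) -> dict:
    """Run the full synthetic wound experiment; returns a result dict and
    writes measurement/metric/stats CSVs plus a plain-text report.

    Any stage failure removes partial outputs and raises
    :class:`PipelineError` tagged with the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    t_start = time.time()
    try:
        # ------------------------------------------------ simulate
        stage = "simulate"
        from dataclasses import replace as _replace

        from .synth import ABLATED, ADJACENT, CONTROL

        trajectories = {
            "control": CONTROL,
            "ablated": _replace(ABLATED, amplitude=ABLATED.amplitude * config.effect_scale),
            "adjacent": _replace(ADJACENT, amplitude=ADJACENT.amplitude * config.effect_scale),
        }
        scene = make_wound_scene(
            n_control=config.n_control,
            n_ablated=config.n_ablated,
            n_adjacent=config.n_adjacent,
            trajectories=trajectories,
            seed=config.seed,
        )
        clean = render_scene(scene)
        stack = apply_noise_and_bleach(clean, scene.acquisition, seed=config.seed)
        truth = ground_truth_table(scene)
        stack_path = out / "stack.tif"
        write_stack(stack, stack_path)
        written += [stack_path, out / "stack.meta.txt"]
        truth_path = out / "ground_truth.csv"
        _write_csv(truth, truth_path, config)
        written.append(truth_path)
        logger.info("simulate: %d cells, %d frames", len(scene.cells), scene.n_frames)

        # ------------------------------------------------ measure
        stage = "measure"
        if config.quantify_corrected:
            stack_q, _ = correct_stack(stack, channel=0)
        else:
            stack_q = stack  # quantification always on raw intensities
        measured = measure_stack(
            stack_q,
            max_disp_px=config.max_disp_px,
            min_area_px=config.min_area_px,
            threshold_method=config.threshold_method,
            background_method=config.background_method,
            gap_px=config.gap_px,
            width_px=config.band_width_px,
            min_defined_fraction=config.min_defined_fraction,
        )
        meas_path = out / "measurements.csv"
        _write_csv(measured, meas_path, config)
        written.append(meas_path)

        # ------------------------------------------------ metrics
        stage = "metrics"
        times = scene.times_min()
        pre_frames = np.nonzero(times < 0)[0]
        early_frames = np.nonzero((times >= 2) & (times <= 22))[0]
        late_frames = np.nonzero(times >= 120)[0]
        if len(pre_frames) == 0 or len(early_frames) == 0:
            raise ValueError("schedule must include pre-wound and early post-wound frames")

        y0, y1, x0, x1 = scene.da_region
        da_pre = float(np.max(stack.data[pre_frames][:, 0], axis=1)[:, y0:y1, x0:x1].mean())
        da_post = float(np.max(stack.data[early_frames][:, 0], axis=1)[:, y0:y1, x0:x1].mean())
        ctx = NormalizationContext(da_mean_pre=da_pre, da_mean_post=da_post)

        track_map = _match_tracks_to_truth(measured, truth)
        anno = truth[["cell_id", "group", "position_index"]].drop_duplicates("cell_id")
        anno = anno.set_index("cell_id")

        rows = []
        curve_rows = []
        for track_id, grp in measured.groupby("cell_id"):
            if track_id not in track_map:
                continue
            gt_id = track_map[track_id]
            group = anno.loc[gt_id, "group"]
            pos = int(anno.loc[gt_id, "position_index"])
            grp = grp.sort_values("frame")
            nuc = grp.set_index("frame")["nuclear_mean_ekc"]
            pre_vals = [da_normalize(nuc.get(f, math.nan), ctx, "pre") for f in pre_frames]
            post_vals = [da_normalize(nuc.get(f, math.nan), ctx, "post") for f in early_frames]
            late_vals = [da_normalize(nuc.get(f, math.nan), ctx, "post") for f in late_frames]
            pre_mean = float(np.nanmean(pre_vals))
            post_mean = float(np.nanmean(post_vals))
            late_mean = float(np.nanmean(late_vals)) if len(late_vals) else math.nan
            rows.append(
                {
                    "cell_id": gt_id,
                    "group": group,
                    "position_index": pos,
                    "post_pre_ratio_early": post_pre_ratio(post_mean, pre_mean),
                    "post_pre_ratio_late": post_pre_ratio(late_mean, pre_mean)
                    if np.isfinite(late_mean)
                    else math.nan,
                    "nc_ratio_pre_mean": float(
                        np.nanmean(
                            (grp.set_index("frame")["nuclear_mean_ekc"] / grp.set_index("frame")["cyto_mean_ekc"]).reindex(pre_frames)
                        )
                    ),
                }
            )
            # reference-time-normalized early-window curve (Fig-6H-style)
            t_early = times[early_frames]
            v_early = np.array([da_normalize(nuc.get(f, math.nan), ctx, "post") for f in early_frames])
            if np.isfinite(v_early).all():
                curve = ActivityCurve(
                    times=t_early,
                    values=v_early,
                    cell_id=gt_id,
                    group_label=group,
                    position_index=pos,
                )
                curve = normalize_to_reference_time(curve, config.reference_time_min)
                for tt, vv in zip(curve.times, curve.values):
                    curve_rows.append(
                        {
                            "cell_id": gt_id,
                            "group": group,
                            "position_index": pos,
                            "time_min": tt,
                            "metric_name": "nuclear_ekc_norm_ref",
                            "value": vv,
                        }
                    )

        metric_df = pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)
        curve_df = pd.DataFrame(curve_rows)
        metrics_path = out / "metrics.csv"
        _write_csv(pd.concat([metric_df], axis=0), metrics_path, config)
        written.append(metrics_path)
        curves_path = out / "curves.csv"
        _write_csv(curve_df, curves_path, config)
        written.append(curves_path)

        # ------------------------------------------------ stats
        stage = "stats"

        def curves_of(group: str) -> list[ActivityCurve]:
            out_c = []
            for cid, g in curve_df[curve_df["group"] == group].groupby("cell_id"):
                g = g.sort_values("time_min")
                out_c.append(
                    ActivityCurve(
                        times=g["time_min"].to_numpy(),
                        values=g["value"].to_numpy(),
                        cell_id=int(cid),
                        group_label=group,
                        position_index=int(g["position_index"].iloc[0]),
                    )
                )
            return out_c

        stats_rows = []
        control_curves = curves_of("control")
        gc_control = GroupedCurves("control", control_curves)
        for group in ("ablated", "adjacent"):
            cs = curves_of(group)
            if len(cs) < 2 or len(control_curves) < 2:
                continue
            perm = permutation_mean_curve_test(
                gc_control,
                GroupedCurves(group, cs),
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            ks = ks_decision(
                gc_control.pooled_values(),
                GroupedCurves(group, cs).pooled_values(),
                alpha=config.alpha_ks,
            )
            stats_rows.append(
                {
                    "comparison": f"control_vs_{group}",
                    "test": "permutation_mean_curve",
                    "n1": gc_control.n_curves,
                    "n2": len(cs),
                    "statistic": perm.observed_stat,
                    "critical_value": math.nan,
                    "p_value": perm.p_value,
                    "reject": perm.p_value <= config.alpha_default,
                    "seed": config.seed,
                }
            )
            stats_rows.append(
                {
                    "comparison": f"control_vs_{group}",
                    "test": "ks_critical_d",
                    "n1": ks.n1,
                    "n2": ks.n2,
                    "statistic": ks.D,
                    "critical_value": ks.critical_D,
                    "p_value": ks.p_asymptotic,
                    "reject": ks.reject,
                    "seed": config.seed,
                }
            )
        stats_df = pd.DataFrame(stats_rows)
        stats_path = out / "stats.csv"
        _write_csv(stats_df, stats_path, config)
        written.append(stats_path)

        # ------------------------------------------------ report
        stage = "report"
        gmeans = metric_df.groupby("group")["post_pre_ratio_early"].mean()
        glate = metric_df.groupby("group")["post_pre_ratio_late"].mean()
        checks = {
            "early_ordering_ablated_lt_adjacent_lt_control": bool(
                gmeans["ablated"] < gmeans["adjacent"] < gmeans["control"]
            ),
            "early_activation_ablated": bool(gmeans["ablated"] < gmeans["control"]),
            "early_activation_adjacent": bool(gmeans["adjacent"] < gmeans["control"]),
            "late_adjacent_returns": bool(
                abs(glate["adjacent"] - glate["control"])
                < abs(glate["ablated"] - glate["control"])
            ),
            "late_ablated_sustained": bool(glate["ablated"] < glate["control"] * 0.95),
        }
        report_lines = [
            f"ktrquant {__version__} wound experiment report",
            f"config_hash={config.config_hash()} seed={config.seed}",
            f"elapsed_s={time.time() - t_start:.1f}",
            "",
            "group mean post/pre nuclear intensity (early 2-22 min):",
        ]
        for g, v in gmeans.items():
            report_lines.append(f"  {g}: {v:.4f}")
        report_lines.append("group mean post/pre nuclear intensity (late ~3 h):")
        for g, v in glate.items():
            report_lines.append(f"  {g}: {v:.4f}")
        report_lines.append("")
        for name, ok in checks.items():
            report_lines.append(f"{'PASS' if ok else 'FAIL'} {name}")
        report_path = out / "report.txt"
        report_path.write_text("\n".join(report_lines) + "\n")
        written.append(report_path)

        return {
            "group_means_early": gmeans.to_dict(),
            "group_means_late": glate.to_dict(),
            "checks": checks,
            "stats": stats_df,
            "metrics": metric_df,
            "curves": curve_df,
            "measurements": measured,
            "truth": truth,
            "paths": {p.name: p for p in written},
        }
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - stage-tagged rethrow
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise PipelineError(stage, str(err)) from err


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small deterministic fixture set: a tiny rendered stack with
    its sidecar and ground truth, a curve CSV, and a manifest of expected
    values computable from first principles."""
    from .synth import ktr_partition

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = make_wound_scene(
        n_control=1,
        n_ablated=1,
        n_adjacent=1,
        frame_times_min=np.arange(-3.0, 5.0),
        frame_shape=(120, 200),
        activity_noise=False,
        seed=seed,
    )
    stack = render_scene(scene)
    paths = {}
    paths["stack"] = Path(out / "tiny_stack.tif")
    write_stack(stack, paths["stack"])
    paths["sidecar"] = out / "tiny_stack.meta.txt"
    truth = ground_truth_table(scene)
    paths["truth"] = out / "tiny_truth.csv"
    truth.to_csv(paths["truth"], index=False)
    manifest = {
        "seed": seed,
        "partition_E0": ktr_partition(0.0),
        "partition_E1": ktr_partition(1.0),
        "partition_E05": ktr_partition(0.5),
        "critical_d_504_189_0.001": ks_critical_d(504, 189, 0.001),
        "n_cells": len(scene.cells),
        "n_frames": scene.n_frames,
        "truth_sha256": hashlib.sha256(paths["truth"].read_bytes()).hexdigest(),
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
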