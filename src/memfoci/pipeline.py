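"""End-to-end pipeline: simulate (optional) → segment → track → classify →
quantify → compare.

``run_pipeline`` chains every stage on one or more scenarios (or on
user-supplied movies), producing per-cell summaries, per-track motion
fits, between-condition comparisons and an optional directory of CSV
tables, boxplot figures and a JSON run manifest.  Identical configuration
and seed give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import msd as msd_mod
from . import quantify as qt
from .config import (MOTION_CLASSES, ImagingConfig, ScenarioConfig,
                     TrackingConfig, _to_plain)
from .segmentation import CellROI, remove_edge_cells, segment_cells
from .simulate import render_movie, simulate_cell_population
from .tracking import (assign_tracks_to_cells, detect_movie, filter_tracks,
                       link_frames)


@dataclass
class ConditionResult:
    """Everything the pipeline measured for one condition."""

    name: str
    detections: pd.DataFrame
    tracks: pd.DataFrame
    fits: pd.DataFrame
    cells: pd.DataFrame
    kinetics: dict
    n_frames: int
    truth: pd.DataFrame | None = None


@dataclass
class PipelineReport:
    conditions: dict[str, ConditionResult]
    comparisons: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def analyze_movie(movie: np.ndarray, bright_field: np.ndarray | None,
                  imaging: ImagingConfig, tracking: TrackingConfig,
                  name: str = "condition",
                  r_conf: float = msd_mod.DEFAULT_R_CONF_UM,
                  rois: list[CellROI] | None = None) -> ConditionResult:
    """Run segmentation, tracking, classification and quantification on
    one movie (pre-segmented ROIs may be passed instead of a bright-field
    image)."""
    try:
        if rois is None:
            if bright_field is None:
                raise ValueError("need a bright-field image or ROIs")
            rois = remove_edge_cells(
                segment_cells(bright_field, imaging),
                imaging.image_shape)
    except Exception as e:  # noqa: BLE001 - stage labelling
        raise PipelineError("segment", e) from e

    try:
        detections = detect_movie(movie, imaging, tracking)
        tracks = filter_tracks(link_frames(detections, tracking), tracking)
        tracks = assign_tracks_to_cells(tracks, rois, imaging)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("track", e) from e

    try:
        fits = [msd_mod.analyze_track(g, imaging.frame_interval_s, r_conf)
                for _, g in tracks.groupby("track_id")]
        fits_df = msd_mod.fits_to_frame(fits)
        kinetics = msd_mod.summarize_kinetics(fits)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classify", e) from e

    try:
        cells_df = summarize_cells(detections, tracks, fits_df, rois,
                                   imaging, len(movie))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("quantify", e) from e

    return ConditionResult(name=name, detections=detections, tracks=tracks,
                           fits=fits_df, cells=cells_df, kinetics=kinetics,
                           n_frames=len(movie))


def summarize_cells(detections: pd.DataFrame, tracks: pd.DataFrame,
                    fits: pd.DataFrame, rois: list[CellROI],
                    imaging: ImagingConfig, n_frames: int) -> pd.DataFrame:
    """One row per (non-edge) cell: area, focus density, mean per-focus
    intensity, per-frame-averaged motion fractions and track count."""
    class_of_track = dict(zip(fits.get("track_id", []),
                              fits.get("motion_class", [])))
    rows = []
    for roi in rois:
        cell_tracks = tracks[tracks["cell_label"] == roi.label] \
            if len(tracks) else tracks
        density = qt.focus_density(detections, roi, imaging, n_frames)
        n_tracks = cell_tracks["track_id"].nunique() if len(cell_tracks) else 0
        if n_tracks:
            intensity = float(qt.focus_intensity_summary(cell_tracks)
                              ["mean_intensity"].mean())
        else:
            intensity = math.nan
        fractions = qt.motion_fractions(cell_tracks, class_of_track)
        row = {"cell_label": roi.label, "area_um2": roi.area_um2,
               "focus_density_per_um2": density,
               "mean_focus_intensity": intensity, "n_tracks": n_tracks}
        row.update({f"frac_{cls}": fractions[cls] for cls in MOTION_CLASSES})
        rows.append(row)
    return pd.DataFrame(rows)


def run_condition(scenario: ScenarioConfig, imaging: ImagingConfig,
                  tracking: TrackingConfig, seed: int) -> ConditionResult:
    """Simulate, render and analyse one scenario."""
    try:
        rng = np.random.default_rng(seed)
        truth, cells = simulate_cell_population(scenario, imaging, rng)
        movie, bright_field = render_movie(truth, imaging, rng, cells=cells)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e
    result = analyze_movie(movie, bright_field, imaging, tracking,
                           name=scenario.name)
    result.truth = truth
    return result


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(scenarios: list[ScenarioConfig],
                 imaging: ImagingConfig | None = None,
                 tracking: TrackingConfig | None = None,
                 seed: int = 0,
                 out_dir: str | Path | None = None,
                 make_plots: bool = False) -> PipelineReport:
    """Run the full pipeline on one or more scenarios and compare the
    first two conditions (density, intensity, constrained fraction)."""
    imaging = imaging or ImagingConfig()
    tracking = tracking or TrackingConfig()
    conditions: dict[str, ConditionResult] = {}
    for i, scen in enumerate(scenarios):
        conditions[scen.name] = run_condition(scen, imaging, tracking,
                                              seed=seed + 1000 * i)

    comparisons: list[dict] = []
    if len(scenarios) >= 2:
        a = conditions[scenarios[0].name]
        b = conditions[scenarios[1].name]
        pairs = [
            ("focus_density_per_um2",
             a.cells["focus_density_per_um2"], b.cells["focus_density_per_um2"]),
            ("mean_focus_intensity",
             a.cells["mean_focus_intensity"], b.cells["mean_focus_intensity"]),
            ("frac_constrained",
             a.cells["frac_constrained"], b.cells["frac_constrained"]),
        ]
        for name, g1, g2 in pairs:
            g1 = np.asarray(g1, float)
            g2 = np.asarray(g2, float)
            if np.isfinite(g1).sum() and np.isfinite(g2).sum():
                comparisons.append(qt.compare_metric(name, g1, g2))

    manifest = {
        "seed": seed,
        "imaging": _to_plain(imaging),
        "tracking": _to_plain(tracking),
        "scenarios": [_to_plain(s) for s in scenarios],
    }
    manifest["config_hash"] = _config_hash(manifest)
    report = PipelineReport(conditions=conditions, comparisons=comparisons,
                            manifest=manifest)
    if out_dir is not None:
        write_report(report, out_dir, make_plots=make_plots)
    return report


def write_report(report: PipelineReport, out_dir: str | Path,
                 make_plots: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, cond in report.conditions.items():
        cond.cells.to_csv(out / f"{name}_cells.csv", index=False)
        cond.tracks.to_csv(out / f"{name}_tracks.csv", index=False)
        cond.fits.to_csv(out / f"{name}_fits.csv", index=False)
    (out / "comparisons.json").write_text(
        json.dumps(report.comparisons, indent=2, default=str))
    (out / "run_manifest.json").write_text(
        json.dumps(report.manifest, indent=2, default=str))
    if make_plots:
        _write_boxplots(report, out)


def _write_boxplots(report: PipelineReport, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [("focus_density_per_um2", "foci per um^2"),
               ("mean_focus_intensity", "mean 3x3 intensity (counts)"),
               ("frac_constrained", "constrained fraction")]
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 4))
    for ax, (col, label) in zip(np.atleast_1d(axes), metrics):
        data, names = [], []
        for name, cond in report.conditions.items():
            vals = cond.cells[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals):
                data.append(vals)
                names.append(name)
        if data:
            ax.boxplot(data, tick_labels=names, whis=1.5)
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(out / "boxplots.png", dpi=120)
    plt.close(fig)
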