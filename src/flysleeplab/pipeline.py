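"""End-to-end pipeline runs: config in, CSV/TIFF/PNG bundle out.

A single YAML config drives each run; the fully resolved config is
copied into the output directory together with a log of the software
version, config hash and any exclusions, so a result folder is
self-describing. Outputs are deterministic for a fixed config and
input set: rerunning produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dam_io import (
    DamDialect,
    ExperimentDesign,
    annotate_timeline,
    filter_dead_flies,
    parse_dam_files,
    series_to_frame,
)
from .sleep_compare import compare_to_controls, per_fly_baseline_delta, results_to_frame
from .sleep_core import (
    all_period_metrics,
    metrics_to_frame,
    score_sleep,
    sleep_profile_binned,
)
from .stats import mean_sem
from .trace_analysis import analyze_trace, group_response_summary, traces_from_frame

__all__ = [
    "RunConfig",
    "design_from_dict",
    "design_to_dict",
    "run_sleep_pipeline",
    "run_tempshift_pipeline",
    "run_trace_pipeline",
    "run_coloc_pipeline",
]


@dataclass
class RunConfig:
    """One pipeline run: input paths, design, options, output directory."""

    kind: str
    inputs: dict[str, Any]
    design: ExperimentDesign | None
    options: dict[str, Any]
    out_dir: Path
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design = (
            design_from_dict(raw["design"]) if "design" in raw else None
        )
        return cls(
            kind=raw["kind"],
            inputs=raw.get("inputs", {}),
            design=design,
            options=raw.get("options", {}),
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "kind": self.kind,
            "inputs": dict(self.inputs),
            "options": dict(self.options),
            "out_dir": str(self.out_dir),
            "seed": self.seed,
        }
        if self.design is not None:
            d["design"] = design_to_dict(self.design)
        return d


def design_from_dict(d: Mapping[str, Any]) -> ExperimentDesign:
    """Build an ExperimentDesign from its YAML form."""
    lights_on = d["lights_on"]
    if isinstance(lights_on, str):
        h, m = lights_on.split(":")[:2]
        lights_on = time(int(h), int(m))
    phases = tuple(
        (str(p[0]), int(p[1]), float(p[2])) for p in d["phases"]
    )
    channels = {
        int(ch): tuple(str(v) for v in spec)
        for ch, spec in d["channels"].items()
    }
    return ExperimentDesign(
        lights_on=lights_on, phase_schedule=phases, channel_map=channels
    )


def design_to_dict(design: ExperimentDesign) -> dict:
    return {
        "lights_on": design.lights_on.strftime("%H:%M"),
        "phases": [list(p) for p in design.phase_schedule],
        "channels": {
            ch: list(spec) for ch, spec in sorted(design.channel_map.items())
        },
    }


def _write_bundle_metadata(config: RunConfig, extra_log: list[str]) -> None:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (out / "config.yaml").write_text(cfg_text)
    # hash identifies the analysis, not where it is written
    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    digest = hashlib.sha256(
        yaml.safe_dump(hashed, sort_keys=True).encode()
    ).hexdigest()[:16]
    lines = [
        f"flysleeplab {__version__}",
        f"config_sha256 {digest}",
        f"kind {config.kind}",
        *extra_log,
    ]
    (out / "run.log").write_text("\n".join(lines) + "\n")


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _load_scored_series(config: RunConfig):
    """Shared front end: parse, annotate, filter, score."""
    assert config.design is not None, "sleep pipelines require a design"
    dialect = DamDialect(**config.options.get("dialect", {}))
    if "dam_files" in config.inputs:
        paths = [Path(p) for p in config.inputs["dam_files"]]
    else:
        paths = [Path(config.inputs["dam_file"])]
    texts = [p.read_text() for p in paths]
    timestamps, counts, missing = parse_dam_files(texts, dialect)
    series = annotate_timeline(timestamps, counts, config.design, missing)
    window_h = float(config.options.get("dead_fly_window_hours", 24.0))
    series, exclusions = filter_dead_flies(series, window_h)
    scored = {
        s.fly_id: score_sleep(s.minutes, s.missing_mask, fly_id=s.fly_id)
        for s in series
    }
    return series, scored, exclusions


def run_sleep_pipeline(config: RunConfig) -> dict[str, Path]:
    """Score sleep and write per-minute, architecture and profile CSVs."""
    series, scored, exclusions = _load_scored_series(config)
    if not series:
        raise ValueError("no flies retained after exclusion filtering")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    bin_minutes = int(config.options.get("bin_minutes", 30))

    _csv(series_to_frame(series), out / "per_minute.csv")

    metric_frames = []
    profile_frames = []
    for s in series:
        rec = scored[s.fly_id]
        metrics = all_period_metrics(rec, s.minutes, s.timeline, s.missing_mask)
        mf = metrics_to_frame(metrics)
        mf.insert(1, "genotype", s.genotype)
        mf.insert(2, "role", s.role)
        metric_frames.append(mf)
        prof = sleep_profile_binned(rec, s.timeline, bin_minutes)
        prof.insert(0, "fly_id", s.fly_id)
        prof.insert(1, "genotype", s.genotype)
        profile_frames.append(prof)
    metrics_df = pd.concat(metric_frames, ignore_index=True)
    _csv(metrics_df, out / "period_metrics.csv")

    prof_df = pd.concat(profile_frames, ignore_index=True)
    # genotype-level profile: per bin, mean +/- SEM across flies of the
    # per-fly day-averaged sleep minutes
    per_fly = (
        prof_df.groupby(["genotype", "fly_id", "bin_index", "zt_start_min"])[
            "sleep_min"
        ]
        .mean()
        .reset_index()
    )
    rows = []
    for (geno, b, zt), grp in per_fly.groupby(
        ["genotype", "bin_index", "zt_start_min"]
    ):
        m, sem = mean_sem(grp["sleep_min"])
        rows.append(
            {
                "genotype": geno,
                "bin_index": b,
                "zt_start_min": zt,
                "mean_sleep_min": m,
                "sem": sem,
                "n_flies": len(grp),
            }
        )
    _csv(pd.DataFrame(rows), out / f"profile_{bin_minutes}min.csv")
    _csv(exclusions, out / "exclusions.csv")
    _write_bundle_metadata(
        config,
        [f"excluded {len(exclusions)} flies", f"retained {len(series)} flies"],
    )
    return {
        "per_minute": out / "per_minute.csv",
        "period_metrics": out / "period_metrics.csv",
        "profile": out / f"profile_{bin_minutes}min.csv",
        "exclusions": out / "exclusions.csv",
    }


def _roles(series) -> dict[str, list[str]]:
    by_role: dict[str, list[str]] = {}
    for s in series:
        by_role.setdefault(s.role, []).append(s.fly_id)
    for role in ("experimental", "gal4_control", "uas_control"):
        if role not in by_role:
            raise ValueError(f"design provides no {role} flies")
    return by_role


def run_tempshift_pipeline(config: RunConfig) -> dict[str, Path]:
    """Temperature-shift analysis: per-fly deltas, control comparisons."""
    assert config.design is not None
    series, scored, exclusions = _load_scored_series(config)
    if not series:
        raise ValueError("no flies retained after exclusion filtering")
    by_role = _roles(series)

    metrics_by_fly = {
        s.fly_id: all_period_metrics(
            scored[s.fly_id], s.minutes, s.timeline, s.missing_mask
        )
        for s in series
    }
    design = config.design
    phases = [design.phase_of_day(d) for d in range(design.n_days)]
    baseline_days = [d for d, p in enumerate(phases) if p == "baseline"]
    if not baseline_days:
        raise ValueError("phase schedule has no 'baseline' phase")
    baseline_day = int(
        config.options.get("baseline_day", baseline_days[-1])
    )
    target_days = [d for d, p in enumerate(phases) if p != "baseline"]

    results = []
    omitted_rows = []
    for day in target_days:
        for light in ("D", "L"):
            deltas_by_role: dict[str, list[float]] = {}
            for role, fly_ids in by_role.items():
                sub = {f: metrics_by_fly[f] for f in fly_ids}
                deltas, omitted = per_fly_baseline_delta(
                    sub, baseline_day, day, light
                )
                deltas_by_role[role] = [d_.delta_sleep_min for d_ in deltas]
                omitted_rows += [
                    {"fly_id": f, "target_day": day, "light": light}
                    for f in omitted
                ]
            res = compare_to_controls(
                deltas_by_role["experimental"],
                deltas_by_role["gal4_control"],
                deltas_by_role["uas_control"],
                target_day=day,
                light=light,
            )
            results.append(res)

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    change_df = results_to_frame(results)
    phase_of = {d: phases[d] for d in target_days}
    change_df.insert(1, "phase", change_df["target_day"].map(phase_of))
    _csv(change_df, out / "sleep_change.csv")
    _csv(pd.DataFrame(omitted_rows, columns=["fly_id", "target_day", "light"]),
         out / "omitted_flies.csv")
    _csv(exclusions, out / "exclusions.csv")
    _write_bundle_metadata(
        config,
        [
            f"baseline_day {baseline_day}",
            f"target_days {target_days}",
            f"excluded {len(exclusions)} flies",
        ],
    )
    return {
        "sleep_change": out / "sleep_change.csv",
        "omitted": out / "omitted_flies.csv",
        "exclusions": out / "exclusions.csv",
    }


def run_trace_pipeline(config: RunConfig) -> dict[str, Path]:
    """Per-ROI responses and gated group statistics from a trace CSV.

    The input table needs columns condition, roi_id, frame, intensity
    (+ channel CFP/YFP for FRET recordings); options carry sensor,
    sample_rate, stimulus timing, ratio orientation and the KW alpha.
    """
    df = pd.read_csv(config.inputs["trace_csv"])
    if df.empty:
        raise ValueError("trace table is empty")
    opts = config.options
    sensor = str(opts.get("sensor", "GCaMP"))
    orientation = str(opts.get("ratio_orientation", "cfp_over_yfp"))
    alpha = float(opts.get("kw_alpha", 0.05))
    f0_mode = str(opts.get("f0_mode", "first"))
    window = opts.get("search_window")
    if window is not None:
        window = (float(window[0]), float(window[1]))

    rows = []
    responses: dict[str, list[float]] = {}
    for condition, grp in df.groupby("condition", sort=True):
        traces = traces_from_frame(
            grp,
            sensor=sensor,
            sample_rate=float(opts.get("sample_rate", 2.0)),
            stimulus_onset_s=float(opts.get("stimulus_onset_s", 30.0)),
            stimulus_duration_s=float(opts.get("stimulus_duration_s", 30.0)),
        )
        for tr in traces:
            stat = analyze_trace(tr, f0_mode, window, orientation)
            rows.append(
                {
                    "condition": condition,
                    "roi_id": tr.roi_id,
                    "polarity": stat.polarity,
                    "max_change_pct": stat.max_change_pct,
                }
            )
            responses.setdefault(str(condition), []).append(
                stat.max_change_pct
            )
    experimental = str(opts.get("experimental", sorted(responses)[0]))
    summary = group_response_summary(responses, experimental, alpha)

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    _csv(pd.DataFrame(rows), out / "responses.csv")
    _csv(summary, out / "group_summary.csv")
    _write_bundle_metadata(
        config,
        [
            f"sensor {sensor}",
            f"ratio_orientation {orientation}",
            f"experimental {experimental}",
        ],
    )
    return {
        "responses": out / "responses.csv",
        "group_summary": out / "group_summary.csv",
    }


def run_coloc_pipeline(config: RunConfig) -> dict[str, Path]:
    """Background-subtract, project, and compute the PDM map for a pair.

    inputs: tiff_r and tiff_g (one multi-page TIFF per channel) and an
    optional mask_tiff; options: background_radius (0 disables),
    projection (sum|max), slice_range.
    """
    import tifffile

    from .coloc_ica import (
        TwoChannelImage,
        compute_pdm,
        pdm_summary,
        render_pdm,
        subtract_background,
        z_project,
    )

    opts = config.options
    stack_r = tifffile.imread(config.inputs["tiff_r"]).astype(float)
    stack_g = tifffile.imread(config.inputs["tiff_g"]).astype(float)
    if stack_r.ndim == 2:
        stack_r = stack_r[None]
    if stack_g.ndim == 2:
        stack_g = stack_g[None]
    radius = float(opts.get("background_radius", 0.0))
    if radius > 0:
        stack_r = subtract_background(stack_r, radius)
        stack_g = subtract_background(stack_g, radius)
    method = str(opts.get("projection", "sum"))
    slice_range = opts.get("slice_range")
    if slice_range is not None:
        slice_range = (int(slice_range[0]), int(slice_range[1]))
    proj_r = z_project(stack_r, method, slice_range)
    proj_g = z_project(stack_g, method, slice_range)
    mask = None
    if "mask_tiff" in config.inputs:
        mask = tifffile.imread(config.inputs["mask_tiff"]) > 0
    pdm_map = compute_pdm(TwoChannelImage(proj_r, proj_g, mask))
    summary = pdm_summary(pdm_map)
    summary.update(
        {
            "mean_r": pdm_map.mean_r,
            "mean_g": pdm_map.mean_g,
            "projection": method,
            "background_radius": radius,
        }
    )
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        out / "pdm_map.tif", pdm_map.pdm.astype(np.float32)
    )
    render_pdm(pdm_map, out / "pdm_map.png")
    _csv(pd.DataFrame([summary]), out / "pdm_summary.csv")
    _write_bundle_metadata(
        config, [f"projection {method}", f"background_radius {radius}"]
    )
    return {
        "pdm_map": out / "pdm_map.tif",
        "pdm_png": out / "pdm_map.png",
        "pdm_summary": out / "pdm_summary.csv",
    }
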