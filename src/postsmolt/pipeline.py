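"""End-to-end orchestration: clean -> distances -> CJS -> timing -> speed -> passage.

Every stage writes plain CSV intermediates into the output directory so a
run can be audited (and resumed) stage by stage; a run log records seeds
and parameters. The final summary table mirrors the per-river-per-year
design summary (N tagged, river/inlet/coastal minimum success).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cleaning, cmr, io as psio, passage, seascape, simulate, speed, timing

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    min_gap_s: float = cleaning.DEFAULT_MIN_GAP_S
    delay_max_s: float = cleaning.DEFAULT_DELAY_MAX_S
    n_boot_chat: int = 100          # scaled-down resample counts for a full run
    median_points: int = 10
    median_reps: int = 20
    delta_max: float = cmr.DELTA_MAX_DEFAULT
    timing_max_tags: int = 500      # subsample cap for the mixed-model fit
    n_sim_intervals: int = 1000
    speed_segments: dict = field(default_factory=lambda: {
        "Oykel": ("Dornoch", "ArrayC"), "Shin": ("Dornoch", "ArrayC"),
        "Cassley": ("Dornoch", "ArrayC"), "Conon": ("Cromarty", "ArrayC"),
        "Ness": ("Chanonry", "ArrayC"),
        "Findhorn": ("FindhornBay", "ArrayC")})
    passage_array: str = "ArrayC"
    passage_rivers: tuple = ("Oykel", "Shin", "Conon", "Ness",
                             "Findhorn", "Spey")


def run_pipeline(bundle: simulate.StudyBundle,
                 config: PipelineConfig | None = None) -> dict:
    """Run every analysis stage on a study bundle; returns a result dict.

    Writes per-stage CSVs plus ``run_log.json`` under ``config.out_dir``.
    """
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {}

    # --- cleaning ---------------------------------------------------------
    cconf = cleaning.CleaningConfig(min_gap=config.min_gap_s,
                                    delay_max=config.delay_max_s)
    cleaned, audit = cleaning.clean(bundle.detections, bundle.deployments, cconf)
    psio.write_table(cleaned, out / "cleaned_detections.csv")
    (out / "cleaning_audit.json").write_text(json.dumps(audit.as_dict(), indent=2))
    results["cleaning_audit"] = audit

    # --- by-water distances ----------------------------------------------
    distances = bundle.distances_km
    distances.to_csv(out / "distances_km.csv")
    results["distances_km"] = distances

    # --- encounter histories, minimum success, CJS model sets --------------
    summary_rows = []
    model_sets = {}
    for name, group in bundle.groups.items():
        hist = cmr.build_encounter_histories(
            cleaned, bundle.deployments, bundle.receivers, group)
        hist.to_csv(out / f"histories_{name}.csv", index=False)
        if len(hist) < 20:
            logger.warning("group %s: only %d histories; skipped", name, len(hist))
            continue
        mset = cmr.fit_model_set(
            hist, group, n_boot=config.n_boot_chat,
            delta_max=config.delta_max,
            median_points=config.median_points,
            median_reps=config.median_reps,
            seed=int(rng.integers(2 ** 31 - 1)))
        mset.table.to_csv(out / f"cjs_models_{name}.csv", index=False)
        mset.averaged.to_csv(out / f"cjs_averaged_{name}.csv", index=False)
        model_sets[name] = (hist, mset)
    results["model_sets"] = model_sets

    # per river-year minimum-success summary
    for name, group in bundle.groups.items():
        hist = cmr.build_encounter_histories(
            cleaned, bundle.deployments, bundle.receivers, group)
        for river in group.rivers:
            for year in sorted(hist["year"].unique()):
                sub = hist[(hist["river"] == river) & (hist["year"] == year)]
                n_tagged = int(((bundle.deployments["river"] == river)
                                & (bundle.deployments["year"] == year)).sum())
                if len(sub) == 0 or n_tagged == 0:
                    continue
                T = group.n_occasions
                row = {"river": river, "year": int(year),
                       "n_tagged": n_tagged,
                       "n_entered": len(sub),
                       "pct_entered": 100.0 * len(sub) / n_tagged}
                if T >= 3:
                    row["inlet_success_pct"] = cmr.min_migration_success(sub, 1)
                if T >= 4:
                    row["coastal_success_pct"] = cmr.min_migration_success(sub, 2)
                summary_rows.append(row)
    summary = pd.DataFrame(summary_rows).sort_values(["river", "year"])
    summary.to_csv(out / "summary_table.csv", index=False)
    results["summary"] = summary

    # --- timing ------------------------------------------------------------
    arrivals = timing.arrival_table(cleaned, bundle.receivers, bundle.deployments)
    arrivals_model = arrivals[arrivals["river"] != "Cassley"]
    tags = arrivals_model["tag_id"].unique()
    if len(tags) > config.timing_max_tags:
        keep = rng.choice(tags, config.timing_max_tags, replace=False)
        arrivals_model = arrivals_model[arrivals_model["tag_id"].isin(keep)]
    psio.write_table(arrivals, out / "arrivals.csv")
    tfit = timing.fit_timing_lmm(arrivals_model)
    intervals = timing.prediction_intervals(
        tfit, n_sim=config.n_sim_intervals,
        seed=int(rng.integers(2 ** 31 - 1)))
    windows = timing.migration_windows(intervals)
    intervals.to_csv(out / "timing_intervals.csv", index=False)
    windows.to_csv(out / "migration_windows.csv", index=False)
    results.update({"timing_fit": tfit, "intervals": intervals,
                    "windows": windows,
                    "window_overlap": timing.window_overlap(windows)})

    # --- speed --------------------------------------------------------------
    speeds = speed.compute_speeds(arrivals, distances, config.speed_segments)
    speeds.to_csv(out / "speeds.csv", index=False)
    smodel = speed.fit_speed_model(speeds)
    smodel.river_means.to_csv(out / "speed_river_means.csv", index=False)
    smodel.lrt_table.to_csv(out / "speed_lrt.csv", index=False)
    results.update({"speeds": speeds, "speed_model": smodel})

    # --- passage -------------------------------------------------------------
    pts = passage.passage_points(arrivals, bundle.receivers, cleaned,
                                 config.passage_array)
    pts = pts[pts["river"].isin(config.passage_rivers)]
    pts.to_csv(out / "passage_points.csv", index=False)
    corridor = passage.empirical_corridor(pts)
    corridor.to_csv(out / "passage_corridor_empirical.csv", index=False)
    n_rec = int(bundle.receivers.loc[
        bundle.receivers["array_id"] == config.passage_array, "rank"].max())
    bdata = pts.assign(y=passage.scale_rank(
        pts["rank"].to_numpy(), 1, n_rec, len(pts)))
    bfit, trail = passage.backward_select(bdata)
    mcorr = passage.model_corridors(bfit, 1, n_rec, len(pts))
    trail.to_csv(out / "passage_lrt_trail.csv", index=False)
    mcorr.to_csv(out / "passage_corridor_model.csv", index=False)
    results.update({"passage_points": pts, "corridor_empirical": corridor,
                    "betareg": bfit, "betareg_trail": trail,
                    "corridor_model": mcorr})

    (out / "run_log.json").write_text(json.dumps({
        "seed": config.seed,
        "min_gap_s": config.min_gap_s,
        "delay_max_s": config.delay_max_s,
        "singleton_window_s": cconf.singleton_window,
        "n_boot_chat": config.n_boot_chat,
        "delta_max": config.delta_max,
        "n_fish": int(len(bundle.deployments)),
    }, indent=2))
    return results
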