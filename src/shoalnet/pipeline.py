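"""End-to-end orchestration: fixes -> contacts -> indicators -> null model
-> timescale curves, with provenance.

Each stage is a thin function over the library modules so the numbered
analysis drivers, the CLI and the tests all share one code path.  The
analysis grid always spans whole days from the first fix's midnight, so
day-shift shuffling preserves time-of-day.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .config import RunConfig, SimulationConfig
from .contacts import events_table
from .indicators import daily_indicators, dyad_indicators, population_average
from .io import read_fixes, write_edge_lists, write_manifest, write_table
from .lake import Lake, lake_from_file
from .networks import aggregate
from .nullmodel import draw_shifts, effect_sizes, shuffle_trajectories
from .preprocess import classify_diel, impute_gaps, pairwise_distances, resample_median
from .timescales import MONTH_HOURS, memory_timescale, timescale_curve


def analysis_grid(fixes: pd.DataFrame) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Whole-day analysis window covering all fixes."""
    t = pd.DatetimeIndex(fixes["timestamp"])
    start = t.min().normalize()
    n_days = int(np.ceil((t.max() - start) / pd.Timedelta(days=1)))
    return start, start + pd.Timedelta(days=max(n_days, 1))


def prepare(fixes: pd.DataFrame, lake: Lake, cfg: RunConfig, override=None):
    """Resample, measure pair distances, impute, classify day/night."""
    start, end = analysis_grid(fixes)
    traj = resample_median(fixes, start=start, end=end)
    dset = impute_gaps(pairwise_distances(traj, use_3d=cfg.use_3d_distance), cfg.impute_max_s)
    calendar = classify_diel(traj.bins, lake.lat, lake.lon, override=override)
    return traj, dset, calendar


def infer_contacts(dset, calendar, cfg: RunConfig) -> pd.DataFrame:
    return events_table(
        dset,
        calendar,
        threshold_m=cfg.distance_threshold_m,
        merge_gap_s=cfg.merge_gap_s,
        min_duration_s=cfg.min_duration_s,
    )


def shuffled_contacts(traj, calendar, cfg: RunConfig, seed: int | None = None):
    """One null replicate: day-shift every fish, rerun the contact pipeline."""
    spec = draw_shifts(
        traj.fish_ids,
        seed=cfg.seed if seed is None else seed,
        max_days=cfg.shift_max_days,
        window_days=traj.n_bins * 15 // 86400,
    )
    straj = shuffle_trajectories(traj, spec)
    sdset = impute_gaps(pairwise_distances(straj, use_3d=cfg.use_3d_distance), cfg.impute_max_s)
    return infer_contacts(sdset, calendar, cfg), spec


def month_windows(bins: pd.DatetimeIndex) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Consecutive 28-day (672 h) blocks covered by the grid."""
    start = bins[0]
    end = bins[-1] + pd.Timedelta(seconds=15)
    out = []
    while start + pd.Timedelta(hours=MONTH_HOURS) <= end:
        out.append((start, start + pd.Timedelta(hours=MONTH_HOURS)))
        start += pd.Timedelta(hours=MONTH_HOURS)
    return out


def run_pipeline(
    cfg: RunConfig,
    sim_cfg: SimulationConfig | None = None,
    fixes: pd.DataFrame | None = None,
    lake: Lake | None = None,
    write: bool = True,
) -> dict:
    """Run every stage; returns the output bundle and (optionally) writes
    CSV tables plus a manifest under ``cfg.output_dir``.

    Input is either a simulation config (synthetic data) or a fix table
    with a lake polygon.  Any stage failure aborts with a stage-labelled
    error.
    """
    seeds = {"pipeline": cfg.seed}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - relabel with stage name
            raise RuntimeError(f"stage '{name}' failed: {e}") from e

    if sim_cfg is not None:
        from .simulate import simulate_population

        fixes, truth = stage("simulate", simulate_population, sim_cfg)
        lake = sim_cfg.lake
        seeds["simulation"] = sim_cfg.rng_seed
    else:
        truth = None
        if fixes is None:
            if cfg.fixes_path is None:
                raise ValueError("either a simulation config or a fix table is required")
            fixes = stage("read_fixes", read_fixes, cfg.fixes_path)
        if lake is None:
            if cfg.lake_path is None:
                raise ValueError(
                    "lake polygon required: distance-from-shore indicator d_i "
                    "and entropy grid need the shoreline"
                )
            lake = lake_from_file(cfg.lake_path, cfg.lake_lat, cfg.lake_lon)

    override = None
    if cfg.diel_override_path:
        override = pd.read_csv(cfg.diel_override_path)

    traj, dset, calendar = stage("preprocess", prepare, fixes, lake, cfg, override)
    events = stage("contacts", infer_contacts, dset, calendar, cfg)
    daily = stage("indicators", daily_indicators, traj, calendar, lake, cfg.entropy_cell_m)
    dyads = stage("indicators", dyad_indicators, events, dset, calendar, cfg.duration_mode)
    pop_daily = population_average(daily, ["T", "d", "S", "v", "h"]) if len(daily) else daily
    pop_dyads = (
        population_average(dyads, ["tau_plus_s", "tau_minus_s", "p"]) if len(dyads) else dyads
    )

    sh_events, shuffle_spec = stage("null_model", shuffled_contacts, traj, calendar, cfg)
    months = month_windows(traj.bins)
    windows = months if months else [(traj.bins[0], traj.bins[-1] + pd.Timedelta(seconds=15))]
    fish_ids = [int(f) for f in traj.fish_ids]
    effects = stage(
        "null_model",
        effect_sizes,
        events,
        sh_events,
        fish_ids,
        windows,
        (None, "day", "night"),
    )

    curves, memories = [], []
    for w in months:
        curve = stage(
            "timescales",
            timescale_curve,
            events,
            sh_events,
            fish_ids,
            w,
            None,
            cfg.ladder_hours,
            cfg.seed,
        )
        curve.insert(0, "window_start", w[0])
        curves.append(curve)
        memories.append(
            {"window_start": w[0], "memory_timescale_h": memory_timescale(curve)}
        )
    curves_df = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
    memory_df = pd.DataFrame(memories)

    bundle = {
        "fixes": fixes,
        "truth": truth,
        "trajectories": traj,
        "distances": dset,
        "calendar": calendar,
        "events": events,
        "shuffled_events": sh_events,
        "shuffle_spec": shuffle_spec,
        "daily_indicators": daily,
        "dyad_indicators": dyads,
        "population_daily": pop_daily,
        "population_dyads": pop_dyads,
        "effect_sizes": effects,
        "timescale_curves": curves_df,
        "memory_timescales": memory_df,
    }

    if write:
        os.makedirs(cfg.output_dir, exist_ok=True)
        out = cfg.output_dir
        counts = {}
        ev_out = events.drop(columns=["first_bin", "last_bin"], errors="ignore")
        sh_out = sh_events.drop(columns=["first_bin", "last_bin"], errors="ignore")
        for name, df in [
            ("contact_events", ev_out),
            ("shuffled_contact_events", sh_out),
            ("daily_indicators", daily),
            ("dyad_indicators", dyads),
            ("population_daily", pop_daily),
            ("population_dyads", pop_dyads),
            ("effect_sizes", effects),
            ("timescale_curves", curves_df),
            ("memory_timescales", memory_df),
        ]:
            write_table(df, os.path.join(out, f"{name}.csv"))
            counts[name] = len(df)
        nets = [
            aggregate(events, fish_ids, w, p)
            for w in windows
            for p in ("day", "night")
        ]
        write_edge_lists(nets, os.path.join(out, "edge_lists.csv"))
        counts["edge_lists"] = sum(g.number_of_edges() for g in nets)
        config_record = cfg.to_dict()
        if sim_cfg is not None:
            config_record["simulation"] = {
                k: v for k, v in vars(sim_cfg).items() if k != "lake"
            }
        bundle["manifest"] = write_manifest(
            out, config_record, {**seeds, "shifts": shuffle_spec.shifts}, counts
        )
    return bundle
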