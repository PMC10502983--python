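"""Daily behavioural indicators per fish and social indicators per dyad.

Individual indicators, per fish, solar day (sunrise-to-sunrise) and diel
period: mean water temperature T, mean distance from shore d, 2-D spatial
Shannon entropy S over 10 m x 10 m cells, mean speed v and mean depth h.
Dyadic indicators, per pair, day and period: mean interaction duration
tau_plus, mean time between interactions tau_minus, and interaction
probability p (fraction of detected bins spent inside a contact event).
Population averages are arithmetic means over fish/pairs with defined
values; undefined values are excluded, never zero-filled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import BIN_SECONDS
from .lake import Lake
from .preprocess import MISSING, DielCalendar, DistanceSet, TrajectorySet


def spatial_entropy(
    x: np.ndarray,
    y: np.ndarray,
    cell_size_m: float = 10.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Shannon entropy (natural log) of occupancy over square grid cells.

    c_m is the fraction of valid bins spent in cell m; S = -sum c_m ln c_m
    over occupied cells.  Undefined (NaN) when no valid bin is given.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        return float("nan")
    ix = np.floor((x[ok] - origin[0]) / cell_size_m).astype(np.int64)
    iy = np.floor((y[ok] - origin[1]) / cell_size_m).astype(np.int64)
    _, counts = np.unique(ix + (iy - iy.min()) * (ix.max() - ix.min() + 2), return_counts=True)
    c = counts / counts.sum()
    return float(-(c * np.log(c)).sum())


def speed_series(traj: TrajectorySet) -> np.ndarray:
    """Per-bin speed (m/s): displacement from the previous bin / 15 s.

    Defined only where both the bin and its predecessor are valid; bin 0
    and bins following a gap are NaN.  Uses 3-D displacement.
    """
    dx = np.diff(traj.x, axis=0)
    dy = np.diff(traj.y, axis=0)
    dz = np.diff(traj.depth, axis=0)
    v = np.sqrt(dx * dx + dy * dy + dz * dz) / BIN_SECONDS
    out = np.full_like(traj.x, np.nan)
    both = traj.valid[1:] & traj.valid[:-1]
    out[1:][both] = v[both]
    return out


def daily_indicators(
    traj: TrajectorySet,
    calendar: DielCalendar,
    lake: Lake | None = None,
    cell_size_m: float = 10.0,
) -> pd.DataFrame:
    """T, d, S, v, h per (fish, solar day, diel period).

    Entropy cells are anchored at the lake bounding-box corner (falling
    back to the data bounding box when no lake is given); distance from
    shore requires a lake polygon.
    """
    if lake is not None:
        minx, miny, _, _ = lake.polygon.bounds
        origin = (minx, miny)
        ext = np.asarray(lake.polygon.exterior.coords)[:-1]
        from ._kernels import dist_to_boundary

        d_shore = np.full_like(traj.x, np.nan)
        m = traj.valid
        d_shore[m] = dist_to_boundary(
            traj.x[m].astype(float), traj.y[m].astype(float),
            np.ascontiguousarray(ext[:, 0]), np.ascontiguousarray(ext[:, 1]),
        )
    else:
        origin = (np.nanmin(traj.x), np.nanmin(traj.y))
        d_shore = None
    v = speed_series(traj)
    period = calendar.period
    rows = []
    keys = pd.DataFrame({"solar_day": calendar.solar_day, "period": period})
    for (day, per), idx in keys.groupby(["solar_day", "period"]).groups.items():
        idx = np.asarray(idx)
        for k, fid in enumerate(traj.fish_ids):
            ok = traj.valid[idx, k]
            n_ok = int(ok.sum())
            if n_ok == 0:
                continue
            sel = idx[ok]
            rows.append(
                {
                    "fish_id": int(fid),
                    "solar_day": day,
                    "period": per,
                    "T": float(np.nanmean(traj.temp[sel, k])) if np.isfinite(traj.temp[sel, k]).any() else np.nan,
                    "d": float(np.mean(d_shore[sel, k])) if d_shore is not None else np.nan,
                    "S": spatial_entropy(traj.x[sel, k], traj.y[sel, k], cell_size_m, origin),
                    "v": float(np.nanmean(v[idx, k])) if np.isfinite(v[idx, k]).any() else np.nan,
                    "h": float(np.mean(traj.depth[sel, k])),
                    "n_bins": n_ok,
                }
            )
    return pd.DataFrame(rows)


def dyad_indicators(
    events: pd.DataFrame,
    dset: DistanceSet,
    calendar: DielCalendar,
    duration_mode: str = "span",
) -> pd.DataFrame:
    """tau_plus, tau_minus and p per (pair, solar day, diel period).

    tau_plus: mean event duration (span by default; "active" counts only
    active bins).  tau_minus: mean gap between consecutive events of the
    pair within the same day/period.  p: of the bins where the pair is
    detected (distance status not missing), the fraction lying inside an
    event span.  Pairs with no defined value for a quantity carry NaN.
    """
    dur_col = "duration_s" if duration_mode == "span" else "active_s"
    n_bins = len(dset.bins)
    keys = pd.DataFrame({"solar_day": calendar.solar_day, "period": calendar.period})
    group_idx = {k: np.asarray(v) for k, v in keys.groupby(["solar_day", "period"]).groups.items()}

    in_event = np.zeros((n_bins, dset.n_pairs), dtype=bool)
    pair_col = {p: j for j, p in enumerate(dset.pairs)}
    if len(events):
        for a, b, fb, lb in events[["pair_a", "pair_b", "first_bin", "last_bin"]].itertuples(
            index=False
        ):
            in_event[fb : lb + 1, pair_col[(a, b)]] = True

    detected = dset.status != MISSING
    rows = []
    ev_groups = (
        events.groupby(["pair_a", "pair_b", "solar_day", "period"])
        if len(events)
        else None
    )
    for (day, per), idx in group_idx.items():
        det = detected[idx]
        act = in_event[idx]
        for j, (a, b) in enumerate(dset.pairs):
            n_det = int(det[:, j].sum())
            if n_det == 0:
                continue
            p = float(act[det[:, j], j].mean())
            tau_p = tau_m = np.nan
            if ev_groups is not None and (a, b, day, per) in ev_groups.groups:
                ev = ev_groups.get_group((a, b, day, per)).sort_values("start")
                tau_p = float(ev[dur_col].mean())
                if len(ev) > 1:
                    gaps = (
                        ev["start"].values[1:] - ev["end"].values[:-1]
                    ) / np.timedelta64(1, "s")
                    tau_m = float(gaps.mean())
            rows.append(
                {
                    "pair_a": a,
                    "pair_b": b,
                    "solar_day": day,
                    "period": per,
                    "tau_plus_s": tau_p,
                    "tau_minus_s": tau_m,
                    "p": p,
                    "n_detected_bins": n_det,
                }
            )
    return pd.DataFrame(rows)


def population_average(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Population averages per (solar day, period), dropping the fish/pair
    index: arithmetic mean over rows with defined values."""
    return table.groupby(["solar_day", "period"])[columns].mean().reset_index()
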