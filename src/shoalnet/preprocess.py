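"""From raw fixes to regular trajectories, distance series and diel labels.

The analysis grid is a gap-free 15 s time grid.  Raw burst-rate fixes are
median-filtered onto it (30 s centred window), pairwise 3-D distances are
computed where both fish have valid bins, and interior gaps of up to 30
minutes are linearly imputed on the *distance* series (not coordinates).
Each bin is classified day or night by solar elevation at the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .config import BIN_SECONDS
from .solar import solar_elevation, sun_events

# status codes for distance bins
MEASURED, IMPUTED, MISSING = 0, 1, 2


@dataclass
class TrajectorySet:
    """Regular per-fish trajectories on a shared, gap-free 15 s grid.

    Arrays are (n_bins, n_fish); invalid bins hold NaN and are flagged in
    ``valid``.  ``bins`` are bin-start timestamps.
    """

    bins: pd.DatetimeIndex
    fish_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    depth: np.ndarray
    temp: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bins) > 1:
            steps = np.diff(self.bins.values) / np.timedelta64(1, "s")
            if not np.all(steps == BIN_SECONDS):
                raise ValueError("bins must form a gap-free 15 s grid")

    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class DistanceSet:
    """Inter-fish distance series for all N(N-1)/2 unordered pairs.

    ``dist`` is (n_bins, n_pairs) metres; ``status`` marks each bin
    MEASURED, IMPUTED or MISSING.  ``pairs`` lists (fish_a, fish_b) with
    a < b, in the same column order.
    """

    bins: pd.DatetimeIndex
    pairs: list[tuple[int, int]]
    dist: np.ndarray
    status: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class DielCalendar:
    """Day/night label per bin plus sunrise/sunset per solar cycle.

    ``solar_day`` labels each bin with the civil date of the most recent
    sunrise, so a night spans midnight without changing label.
    """

    bins: pd.DatetimeIndex
    is_day: np.ndarray
    events: pd.DataFrame  # date, sunrise, sunset
    solar_day: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.solar_day is None:
            sunrises = self.events["sunrise"].values
            idx = np.searchsorted(sunrises, self.bins.values, side="right") - 1
            idx = np.clip(idx, 0, len(sunrises) - 1)
            self.solar_day = self.events["date"].dt.date.values[idx]

    @property
    def period(self) -> np.ndarray:
        return np.where(self.is_day, "day", "night")


def _median_filter_one_fish(
    seconds: np.ndarray, values: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-wise median of fixes in centred half-open windows.

    A fix at offset s (relative to grid start) lies in bin b's window
    [b*15-15, b*15+15) exactly for b in {floor(s/15), floor(s/15)+1}.
    """
    q = np.floor_divide(seconds, BIN_SECONDS).astype(np.int64)
    bins2 = np.concatenate([q, q + 1])
    vals2 = np.concatenate([values, values], axis=0)
    keep = (bins2 >= 0) & (bins2 < n_bins)
    bins2, vals2 = bins2[keep], vals2[keep]
    out = np.full((n_bins, values.shape[1]), np.nan)
    if len(bins2) == 0:
        return out, np.zeros(n_bins, dtype=bool)
    med = pd.DataFrame(vals2, index=bins2).groupby(level=0).median()
    out[med.index.to_numpy()] = med.to_numpy()
    valid = np.zeros(n_bins, dtype=bool)
    valid[med.index.to_numpy()] = True
    return out, valid


def resample_median(
    fixes: pd.DataFrame,
    start: pd.Timestamp | None = None,
    end: pd.Timestamp | None = None,
) -> TrajectorySet:
    """Median-filter raw fixes onto the 15 s analysis grid.

    Each bin value is the coordinate-wise median of the fixes in the
    centred 30 s window [t-15 s, t+15 s); bins whose window holds no fix
    are flagged missing.  Duplicate (fish, timestamp) records with
    conflicting coordinates are rejected.
    """
    fixes = fixes.sort_values(["fish_id", "timestamp"], kind="mergesort")
    dup = fixes.duplicated(subset=["fish_id", "timestamp"], keep=False)
    if dup.any():
        d = fixes[dup]
        spread = d.groupby(["fish_id", "timestamp"])[["x_m", "y_m", "depth_m"]].agg(
            lambda s: s.max() - s.min()
        )
        if (spread.to_numpy() > 0).any():
            raise ValueError("duplicate (fish, timestamp) fixes with conflicting coordinates")
        fixes = fixes.drop_duplicates(subset=["fish_id", "timestamp"])

    t = pd.DatetimeIndex(fixes["timestamp"])
    if start is None:
        start = t.min().floor(f"{BIN_SECONDS}s")
    if end is None:
        end = t.max().ceil(f"{BIN_SECONDS}s") + pd.Timedelta(seconds=BIN_SECONDS)
    bins = pd.date_range(start, end, freq=f"{BIN_SECONDS}s", inclusive="left")
    n_bins = len(bins)

    fish_ids = np.sort(fixes["fish_id"].unique())
    cols = ["x_m", "y_m", "depth_m", "temp_c"]
    has_temp = "temp_c" in fixes.columns
    use_cols = cols if has_temp else cols[:3]
    shape = (n_bins, len(fish_ids))
    x = np.full(shape, np.nan)
    y = np.full(shape, np.nan)
    depth = np.full(shape, np.nan)
    temp = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for k, fid in enumerate(fish_ids):
        sub = fixes[fixes["fish_id"] == fid]
        seconds = (
            pd.DatetimeIndex(sub["timestamp"]).values - start.to_datetime64()
        ) / np.timedelta64(1, "s")
        med, ok = _median_filter_one_fish(seconds, sub[use_cols].to_numpy(float), n_bins)
        x[:, k], y[:, k], depth[:, k] = med[:, 0], med[:, 1], med[:, 2]
        if has_temp:
            temp[:, k] = med[:, 3]
        valid[:, k] = ok
    return TrajectorySet(bins=bins, fish_ids=fish_ids, x=x, y=y, depth=depth, temp=temp, valid=valid)


def pairwise_distances(traj: TrajectorySet, use_3d: bool = True) -> DistanceSet:
    """Euclidean inter-fish distance per bin for every unordered pair.

    3-D by default (x, y, depth); bins where either fish is invalid are
    MISSING.
    """
    pairs = list(combinations(range(traj.n_fish), 2))
    ia = np.array([p[0] for p in pairs], dtype=int)
    ib = np.array([p[1] for p in pairs], dtype=int)
    x32 = traj.x.astype(np.float32)
    y32 = traj.y.astype(np.float32)
    dx = x32[:, ia] - x32[:, ib]
    dy = y32[:, ia] - y32[:, ib]
    d2 = dx * dx + dy * dy
    if use_3d:
        z32 = traj.depth.astype(np.float32)
        dz = z32[:, ia] - z32[:, ib]
        d2 += dz * dz
    dist = np.sqrt(d2)
    ok = traj.valid[:, ia] & traj.valid[:, ib]
    status = np.where(ok, MEASURED, MISSING).astype(np.int8)
    dist[~ok] = np.nan
    pair_ids = [(int(traj.fish_ids[a]), int(traj.fish_ids[b])) for a, b in pairs]
    return DistanceSet(bins=traj.bins, pairs=pair_ids, dist=dist, status=status)


def impute_gaps(dset: DistanceSet, max_gap_s: float = 1800.0) -> DistanceSet:
    """Linearly impute interior missing runs of duration <= max_gap_s.

    A run of k missing bins spans k * 15 s; runs at or under the bound
    (inclusive) are interpolated between the flanking measured values and
    flagged IMPUTED.  Longer runs and leading/trailing runs stay MISSING.
    """
    max_bins = int(max_gap_s // BIN_SECONDS)
    dist = dset.dist.copy()
    status = dset.status.copy()
    n_bins = len(dset.bins)

    # run-length bookkeeping, vectorised over all pairs (column-major flat)
    miss = (status == MISSING).T.ravel()
    col_start = np.zeros(miss.size, dtype=bool)
    col_start[:: n_bins] = True
    prev = np.concatenate([[False], miss[:-1]])
    run_start = miss & (col_start | ~prev)
    rid = np.cumsum(run_start) - 1
    if run_start.any():
        lengths = np.bincount(rid[miss])
        start_idx = np.flatnonzero(run_start)
        end_idx = start_idx + lengths - 1
        interior = (start_idx % n_bins != 0) & ((end_idx + 1) % n_bins != 0)
        ok_run = (lengths <= max_bins) & interior
        eligible = (miss & ok_run[rid]).reshape(dset.n_pairs, n_bins).T
        if eligible.any():
            interp = (
                pd.DataFrame(np.where(status == MISSING, np.nan, dist))
                .interpolate(method="linear", limit_area="inside", axis=0)
                .to_numpy()
            )
            dist[eligible] = interp[eligible].astype(dist.dtype)
            status[eligible] = IMPUTED
    return DistanceSet(bins=dset.bins, pairs=list(dset.pairs), dist=dist, status=status)


def classify_diel(
    bins: pd.DatetimeIndex,
    lat: float,
    lon: float,
    override: pd.DataFrame | None = None,
) -> DielCalendar:
    """Label each 15 s bin day or night.

    Day iff solar elevation > 0 at the bin midpoint.  An override table
    (columns date, sunrise, sunset; UTC) bypasses the solar model
    verbatim.
    """
    if abs(lat) > 66.6:
        raise ValueError("polar day/night unsupported beyond |lat| = 66.6 deg")
    dates = pd.date_range(
        bins[0].normalize() - pd.Timedelta(days=1), bins[-1].normalize(), freq="D"
    )
    if override is not None:
        ev = override.copy()
        ev["date"] = pd.to_datetime(ev["date"])
        ev["sunrise"] = pd.to_datetime(ev["sunrise"])
        ev["sunset"] = pd.to_datetime(ev["sunset"])
        ev = ev.sort_values("date", ignore_index=True)
        t = bins.values + np.timedelta64(BIN_SECONDS * 500, "ms")
        idx = np.searchsorted(ev["sunrise"].values, t, side="right") - 1
        idx_ok = np.clip(idx, 0, len(ev) - 1)
        is_day = (idx >= 0) & (t < ev["sunset"].values[idx_ok]) & (t >= ev["sunrise"].values[idx_ok])
        return DielCalendar(bins=bins, is_day=is_day, events=ev)
    mid = bins + pd.Timedelta(seconds=BIN_SECONDS / 2)
    is_day = solar_elevation(mid, lat, lon) > 0.0
    events = sun_events(dates, lat, lon)
    return DielCalendar(bins=bins, is_day=is_day, events=events)
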