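"""Contact-event inference from inter-fish distance series.

A social interaction is persistent proximity: distance below 10 m
sustained for at least 30 s (two consecutive 15 s bins).  Runs of active
bins separated by breaks of up to 5 min are merged into one event; events
supported by a single active bin are removed, then events spanning less
than 30 s.  The filter order (merge, drop singletons, minimum duration)
means a lone active bin within 5 min of a real event is absorbed into it
rather than deleted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import BIN_SECONDS
from .preprocess import MISSING, DielCalendar, DistanceSet


def threshold_series(dset: DistanceSet, threshold_m: float = 10.0) -> np.ndarray:
    """Binary link activity: bin active iff distance < threshold (strict)
    and the bin is not missing.  Returns (n_bins, n_pairs) bool."""
    if threshold_m <= 0:
        raise ValueError("threshold must be positive")
    with np.errstate(invalid="ignore"):
        active = dset.dist < threshold_m
    active &= dset.status != MISSING  # NaN distances already compare False
    return active


def _runs(active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of True: (starts, ends) bin indices, ends exclusive."""
    d = np.diff(np.concatenate([[0], active.astype(np.int8), [0]]))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def merge_and_filter(
    active: np.ndarray,
    merge_gap_s: float = 300.0,
    min_duration_s: float = 30.0,
) -> list[tuple[int, int, int]]:
    """Contact events for one pair's binary activity series.

    Returns (first_bin, last_bin_exclusive, n_active_bins) triples after:
    (1) maximal active runs become candidates; (2) candidates whose
    inter-gap is <= merge_gap_s are merged (gap bins stay inside the
    span); (3) events supported by one active bin are dropped; (4) events
    spanning < min_duration_s are dropped.
    """
    starts, ends = _runs(np.asarray(active, dtype=bool))
    if len(starts) == 0:
        return []
    gap_bins = int(merge_gap_s // BIN_SECONDS)
    merged: list[list[int]] = [[starts[0], ends[0], ends[0] - starts[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= gap_bins:
            merged[-1][1] = e
            merged[-1][2] += e - s
        else:
            merged.append([s, e, e - s])
    min_bins = int(np.ceil(min_duration_s / BIN_SECONDS))
    return [
        (s, e, n)
        for s, e, n in merged
        if n > 1 and (e - s) >= min_bins
    ]


def events_table(
    dset: DistanceSet,
    calendar: DielCalendar | None = None,
    threshold_m: float = 10.0,
    merge_gap_s: float = 300.0,
    min_duration_s: float = 30.0,
) -> pd.DataFrame:
    """Run the full contact pipeline over every pair.

    Columns: pair_a, pair_b, start, end, duration_s (span, = end - start),
    active_s (active-bin time), n_bins, first_bin, last_bin, and — when a
    calendar is given — period and solar_day of the start bin.  Events of
    one pair are non-overlapping and separated by > merge_gap_s.
    """
    active = threshold_series(dset, threshold_m)
    bins = dset.bins
    rows = []
    for j, (a, b) in enumerate(dset.pairs):
        for s, e, n in merge_and_filter(active[:, j], merge_gap_s, min_duration_s):
            rows.append((a, b, s, e, n))
    if not rows:
        cols = ["pair_a", "pair_b", "start", "end", "duration_s", "active_s", "n_bins"]
        if calendar is not None:
            cols += ["period", "solar_day"]
        return pd.DataFrame(columns=cols)
    arr = np.array(rows, dtype=int)
    df = pd.DataFrame(
        {
            "pair_a": arr[:, 0],
            "pair_b": arr[:, 1],
            "start": bins[arr[:, 2]],
            "end": bins[arr[:, 3] - 1] + pd.Timedelta(seconds=BIN_SECONDS),
            "duration_s": (arr[:, 3] - arr[:, 2]) * BIN_SECONDS,
            "active_s": arr[:, 4] * BIN_SECONDS,
            "n_bins": arr[:, 4],
            "first_bin": arr[:, 2],
            "last_bin": arr[:, 3] - 1,
        }
    )
    if calendar is not None:
        df["period"] = calendar.period[arr[:, 2]]
        df["solar_day"] = calendar.solar_day[arr[:, 2]]
    return df.sort_values(["pair_a", "pair_b", "start"], ignore_index=True)
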