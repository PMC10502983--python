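"""Configuration objects for the simulator and the analysis pipeline."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .lake import Lake, default_lake

REGIMES = ("winter", "summer", "transition")

#: Analysis bin width in seconds; the contact pipeline operates on this grid.
BIN_SECONDS = 15


@dataclass
class SeasonSchedule:
    """Maps day-of-year to a seasonal regime via four boundary days.

    winter: doy < winter_end or doy >= winter_start;
    summer: summer_start <= doy < summer_end; transition otherwise.
    """

    winter_end: int = 80
    summer_start: int = 125
    summer_end: int = 265
    winter_start: int = 325

    def regime(self, day_of_year: np.ndarray) -> np.ndarray:
        doy = np.asarray(day_of_year)
        out = np.full(doy.shape, "transition", dtype=object)
        out[(doy < self.winter_end) | (doy >= self.winter_start)] = "winter"
        out[(doy >= self.summer_start) & (doy < self.summer_end)] = "summer"
        return out


@dataclass
class SimulationConfig:
    """Generative parameters for telemetry-like trajectories.

    Movement is a correlated random walk with a social-attraction pull
    toward the current group centroid plus a diel radial habitat bias.
    ``attraction_strength`` is a relaxation rate (1/s): the fraction of
    the fish-to-centroid vector closed per second, so 1/attraction_strength
    is the e-folding time of group cohesion.  Biases are fractions of the
    current cruising speed directed along the shore-to-centre axis.
    ``site_fidelity`` (1/s) is a weak pull toward the group's littoral
    site anchor — persistent groups hold distinct sites, so the anchors
    keep them spatially separable; it is part of the social process and
    inactive when attraction_strength is zero.
    """

    n_fish: int = 25
    duration_days: int = 14
    burst_interval_s: int = 5
    lake: Lake = field(default_factory=default_lake)
    n_groups: int = 3
    group_switch_timescale_h: float = 48.0
    attraction_strength: float = 0.03
    speed_day: Mapping[str, float] = field(
        default_factory=lambda: {"winter": 1.0, "summer": 0.5, "transition": 0.7}
    )
    speed_night: Mapping[str, float] = field(
        default_factory=lambda: {"winter": 0.35, "summer": 0.3, "transition": 0.3}
    )
    offshore_bias_day: float = 0.5
    littoral_bias_night: float = 0.5
    site_fidelity: float = 0.002
    detection_yield_base: float = 0.4
    detection_yield_summer_day_penalty: float = 0.15
    reed_attenuation: float = 0.5
    season_schedule: SeasonSchedule = field(default_factory=SeasonSchedule)
    start: str = "2021-01-01T00:00:00"
    heading_sigma: float = 0.15
    depth_deep_m: float = 5.0
    depth_shallow_m: float = 1.0
    depth_relax_per_s: float = 0.005
    depth_sigma: float = 0.05
    max_depth_m: float = 7.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if 60 % self.burst_interval_s != 0:
            raise ValueError("burst_interval_s must divide 60")
        for name in (
            "detection_yield_base",
            "detection_yield_summer_day_penalty",
            "reed_attenuation",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.attraction_strength < 0:
            raise ValueError("attraction_strength must be >= 0")
        numeric = [
            self.attraction_strength,
            self.offshore_bias_day,
            self.littoral_bias_night,
            self.group_switch_timescale_h,
            *self.speed_day.values(),
            *self.speed_night.values(),
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("non-finite simulation parameter")
        min_spacing_area = self.n_fish * 5.0**2
        if self.lake.area_m2 < min_spacing_area:
            raise ValueError("lake polygon too small for n_fish at 5 m minimum spacing")

    @property
    def n_steps(self) -> int:
        total = self.duration_days * 86400
        if total % self.burst_interval_s != 0:
            raise ValueError("duration must be a whole number of burst intervals")
        return total // self.burst_interval_s

    @property
    def start_time(self) -> pd.Timestamp:
        return pd.Timestamp(self.start)

    def max_speed(self) -> float:
        """Upper bound on realised speed (cruise + attraction + bias cap)."""
        return 2.0 * max(*self.speed_day.values(), *self.speed_night.values())


@dataclass
class RunConfig:
    """Thresholds and paths for the full inference pipeline.

    Defaults are the study constants: 10 m proximity threshold, 30 s
    minimum contact, 5 min merge gap, 30 min imputation bound, 10 m
    entropy cells, 0-6 whole-day null shifts.
    """

    distance_threshold_m: float = 10.0
    min_duration_s: float = 30.0
    merge_gap_s: float = 300.0
    impute_max_s: float = 1800.0
    entropy_cell_m: float = 10.0
    shift_max_days: int = 6
    use_3d_distance: bool = True
    duration_mode: str = "span"  # "span" counts merged gaps; "active" counts active bins
    ladder_hours: tuple[int, ...] = (672, 336, 168, 84, 48, 24, 12, 6, 3, 1)
    seed: int = 0
    fixes_path: str | None = None
    lake_path: str | None = None
    lake_lat: float | None = None
    lake_lon: float | None = None
    diel_override_path: str | None = None
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name in (
            "distance_threshold_m",
            "min_duration_s",
            "merge_gap_s",
            "impute_max_s",
            "entropy_cell_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration_mode not in ("span", "active"):
            raise ValueError("duration_mode must be 'span' or 'active'")

    def to_dict(self) -> dict:
        return asdict(self)


def run_config_from_file(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) if path.endswith((".yml", ".yaml")) else json.load(fh)
    if "ladder_hours" in data:
        data["ladder_hours"] = tuple(data["ladder_hours"])
    return RunConfig(**data)
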