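"""Daily behavioural and social indicators, split day/night.

Per fish and solar day: temperature T, distance from shore d, spatial
entropy S, speed v, depth h.  Per pair: mean interaction duration tau+,
mean time between interactions tau-, interaction probability p.  Writes
per-individual tables and population averages.
"""

import os

from shoalnet.config import RunConfig
from shoalnet.indicators import (
    daily_indicators,
    dyad_indicators,
    population_average,
)
from shoalnet.io import read_fixes, write_table
from shoalnet.lake import lake_from_file
from shoalnet.pipeline import infer_contacts, prepare

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    fixes = read_fixes(os.path.join(OUT, "fixes.csv"))
    lake = lake_from_file(os.path.join(OUT, "lake.geojson"), lat=52.995, lon=13.582)
    cfg = RunConfig(seed=1)
    traj, dset, cal = prepare(fixes, lake, cfg)
    events = infer_contacts(dset, cal, cfg)

    daily = daily_indicators(traj, cal, lake, cfg.entropy_cell_m)
    dyads = dyad_indicators(events, dset, cal, cfg.duration_mode)
    pop_daily = population_average(daily, ["T", "d", "S", "v", "h"])
    pop_dyads = population_average(dyads, ["tau_plus_s", "tau_minus_s", "p"])

    write_table(daily, os.path.join(OUT, "daily_indicators.csv"))
    write_table(dyads, os.path.join(OUT, "dyad_indicators.csv"))
    write_table(pop_daily, os.path.join(OUT, "population_daily.csv"))
    write_table(pop_dyads, os.path.join(OUT, "population_dyads.csv"))

    for per in ("day", "night"):
        sub = pop_daily[pop_daily["period"] == per].mean(numeric_only=True)
        dsub = pop_dyads[pop_dyads["period"] == per].mean(numeric_only=True)
        print(
            f"{per:>5}: v={sub['v']:.2f} m/s  h={sub['h']:.2f} m  d={sub['d']:.0f} m  "
            f"S={sub['S']:.2f}  p={dsub['p']:.3f}  tau+={dsub['tau_plus_s']:.0f} s"
        )


if __name__ == "__main__":
    main()
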