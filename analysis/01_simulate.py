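"""Generate the synthetic study population.

Simulates one 28-day summer month for 12 carp in the default 25 ha lake:
three social groups with 48 h mean residence, episodic shoaling contact,
~40% detection yield with reed attenuation near shore.  Writes the fix
table, ground-truth group memberships and the lake outline under
results/.
"""

import os

from shoalnet.config import SimulationConfig
from shoalnet.io import write_table
from shoalnet.lake import lake_to_geojson
from shoalnet.simulate import simulate_population

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    cfg = SimulationConfig(
        n_fish=12,
        duration_days=28,
        burst_interval_s=15,
        n_groups=3,
        group_switch_timescale_h=48.0,
        attraction_strength=0.03,
        rng_seed=1,
        start="2021-06-01T00:00:00",
    )
    fixes, truth = simulate_population(cfg)
    os.makedirs(OUT, exist_ok=True)
    write_table(fixes, os.path.join(OUT, "fixes.csv"))
    write_table(truth.segments, os.path.join(OUT, "truth_groups.csv"))
    lake_to_geojson(cfg.lake, os.path.join(OUT, "lake.geojson"))
    yield_pct = 100 * len(fixes) / (cfg.n_steps * cfg.n_fish)
    print(
        f"simulated {cfg.n_fish} fish for {cfg.duration_days} d: "
        f"{len(fixes)} fixes ({yield_pct:.0f}% detection yield), "
        f"{len(truth.segments) - cfg.n_fish} group switches"
    )


if __name__ == "__main__":
    main()
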