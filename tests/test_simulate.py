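"""Generative model: determinism, physical bounds, social structure."""

import numpy as np
import pandas as pd
import pytest

from shoalnet.config import SimulationConfig
from shoalnet.simulate import simulate_population, temperature_field


class TestDeterminism:
    def test_identical_seed_bit_identical_fixes(self, tiny_sim_cfg):
        f1, t1 = simulate_population(tiny_sim_cfg)
        f2, t2 = simulate_population(tiny_sim_cfg)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(t1.segments, t2.segments)

    def test_different_seed_differs(self, tiny_sim_cfg, tiny_sim):
        import dataclasses

        other = dataclasses.replace(tiny_sim_cfg, rng_seed=tiny_sim_cfg.rng_seed + 1)
        f2, _ = simulate_population(other)
        assert not f2.equals(tiny_sim[0])


class TestPhysicalBounds:
    def test_all_fixes_inside_lake(self, tiny_sim_cfg, tiny_sim):
        fixes, _ = tiny_sim
        inside = tiny_sim_cfg.lake.contains_xy(fixes["x_m"].values, fixes["y_m"].values)
        assert inside.all()

    def test_displacement_bounded_by_max_speed(self, tiny_sim_cfg, tiny_sim):
        fixes, _ = tiny_sim
        bound = tiny_sim_cfg.max_speed() * tiny_sim_cfg.burst_interval_s
        for _, sub in fixes.groupby("fish_id"):
            dt = sub["timestamp"].diff().dt.total_seconds().values[1:]
            step = np.hypot(sub["x_m"].diff(), sub["y_m"].diff()).values[1:]
            assert (step <= bound * (dt / tiny_sim_cfg.burst_interval_s) + 1e-6).all()

    def test_depth_non_negative(self, tiny_sim):
        assert (tiny_sim[0]["depth_m"] >= 0).all()


class TestDetectionModel:
    def test_full_yield_no_penalty_emits_every_burst(self, small_lake):
        cfg = SimulationConfig(
            n_fish=3,
            duration_days=1,
            burst_interval_s=15,
            lake=small_lake,
            detection_yield_base=1.0,
            detection_yield_summer_day_penalty=0.0,
            reed_attenuation=0.0,
            rng_seed=0,
            start="2021-06-01T00:00:00",
        )
        fixes, _ = simulate_population(cfg)
        per_fish = fixes.groupby("fish_id").size()
        assert (per_fish == cfg.n_steps).all()

    def test_summer_day_penalty_lowers_yield(self, small_lake):
        base = dict(
            n_fish=4, duration_days=2, burst_interval_s=15, lake=small_lake,
            reed_attenuation=0.0, rng_seed=1, start="2021-07-01T00:00:00",
        )
        full = simulate_population(SimulationConfig(**base))[0]
        penal = simulate_population(
            SimulationConfig(**base, detection_yield_summer_day_penalty=0.3)
        )[0]
        assert len(penal) < len(full)


class TestSocialStructure:
    def test_single_fish_has_no_pairs_downstream(self, small_lake):
        from shoalnet.config import RunConfig
        from shoalnet.pipeline import infer_contacts, prepare

        cfg = SimulationConfig(
            n_fish=1, duration_days=1, burst_interval_s=15, lake=small_lake, rng_seed=2
        )
        fixes, _ = simulate_population(cfg)
        traj, dset, cal = prepare(fixes, small_lake, RunConfig())
        assert dset.n_pairs == 0
        assert len(infer_contacts(dset, cal, RunConfig())) == 0

    def test_truth_partitions_population(self, tiny_sim):
        _, truth = tiny_sim
        times = pd.date_range("2021-06-01", periods=20, freq="2h")
        m = truth.membership_at(times)
        assert m.notna().all().all()
        assert m.shape == (20, 6)
        for _, seg in truth.segments.groupby("fish_id"):
            seg = seg.sort_values("start")
            assert (seg["end"].values[:-1] == seg["start"].values[1:]).all()

    def test_attraction_tightens_nearest_neighbour_distance(self, small_lake):
        medians = []
        for strength in (0.0, 0.01, 0.05):
            cfg = SimulationConfig(
                n_fish=8,
                duration_days=1,
                burst_interval_s=15,
                lake=small_lake,
                n_groups=1,
                attraction_strength=strength,
                detection_yield_base=1.0,
                detection_yield_summer_day_penalty=0.0,
                reed_attenuation=0.0,
                rng_seed=9,
                start="2021-06-01T00:00:00",
            )
            fixes, _ = simulate_population(cfg)
            wide_x = fixes.pivot(index="timestamp", columns="fish_id", values="x_m").values
            wide_y = fixes.pivot(index="timestamp", columns="fish_id", values="y_m").values
            dx = wide_x[:, :, None] - wide_x[:, None, :]
            dy = wide_y[:, :, None] - wide_y[:, None, :]
            d = np.hypot(dx, dy)
            np.einsum("tii->ti", d)[:] = np.inf
            medians.append(np.median(d.min(axis=2)))
        assert medians[0] > medians[1] > medians[2]

    def test_group_switch_rate_matches_timescale(self, small_lake):
        cfg = SimulationConfig(
            n_fish=20,
            duration_days=4,
            burst_interval_s=60,
            lake=small_lake,
            n_groups=3,
            group_switch_timescale_h=8.0,
            rng_seed=3,
        )
        _, truth = simulate_population(cfg)
        n_switches = len(truth.segments) - cfg.n_fish
        expected = cfg.n_fish * cfg.duration_days * 24 / 8.0
        assert n_switches == pytest.approx(expected, rel=0.25)


class TestConfigValidation:
    def test_bad_burst_interval(self, small_lake):
        with pytest.raises(ValueError, match="divide 60"):
            SimulationConfig(burst_interval_s=7, lake=small_lake)

    def test_negative_attraction(self, small_lake):
        with pytest.raises(ValueError, match="attraction"):
            SimulationConfig(attraction_strength=-1.0, lake=small_lake)

    def test_non_finite_speed(self, small_lake):
        with pytest.raises(ValueError, match="finite"):
            SimulationConfig(speed_day={"winter": np.inf, "summer": 1, "transition": 1}, lake=small_lake)

    def test_probability_out_of_range(self, small_lake):
        with pytest.raises(ValueError, match="probability"):
            SimulationConfig(detection_yield_base=1.5, lake=small_lake)

    def test_polygon_too_small(self):
        from shoalnet.lake import Lake, ellipse_polygon

        pond = Lake(polygon=ellipse_polygon(5.0, 5.0), lat=52.0, lon=13.0)
        with pytest.raises(ValueError, match="too small"):
            SimulationConfig(n_fish=30, lake=pond)


class TestTemperatureField:
    def test_surface_warmer_in_summer_than_winter(self):
        assert temperature_field(0.0, 197) > temperature_field(0.0, 15) + 10

    def test_monotone_non_increasing_with_depth_in_summer(self):
        depths = np.linspace(0, 7, 50)
        t = temperature_field(depths, 200)
        assert (np.diff(t) <= 0).all()

    @pytest.mark.parametrize("doy", [15, 350])
    def test_winter_isothermal(self, doy):
        t = temperature_field(np.linspace(0, 7, 50), doy)
        assert t.max() - t.min() <= 0.5

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            temperature_field(-1.0, 100)
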