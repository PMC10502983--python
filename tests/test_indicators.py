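"""Individual and dyadic behavioural indicators."""

import numpy as np
import pandas as pd
import pytest

from shoalnet.config import BIN_SECONDS
from shoalnet.indicators import (
    dyad_indicators,
    population_average,
    spatial_entropy,
    speed_series,
)
from shoalnet.lake import Lake, ellipse_polygon

from conftest import make_distance_set


class TestSpatialEntropy:
    def test_single_cell_zero(self):
        assert spatial_entropy([1.0] * 10, [1.0] * 10) == 0.0

    def test_uniform_four_cells(self):
        x = [5, 15, 5, 15] * 3
        y = [5, 5, 15, 15] * 3
        assert spatial_entropy(x, y) == pytest.approx(np.log(4))

    def test_half_quarter_quarter(self):
        x = [5, 5, 15, 25]
        y = [5] * 4
        # -sum(c ln c) for (1/2, 1/4, 1/4), evaluated directly
        assert spatial_entropy(x, y) == pytest.approx(1.0397, abs=1e-4)

    def test_no_valid_bins_undefined(self):
        assert np.isnan(spatial_entropy([np.nan], [np.nan]))

    def test_point_mass_invariant_under_grid_translation(self):
        x, y = [3.7] * 8, [9.1] * 8
        for ox in (0.0, 1.3, -7.7):
            assert spatial_entropy(x, y, origin=(ox, ox)) == 0.0

    def test_splitting_occupancy_never_decreases_entropy(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 40, 200)
        y = rng.uniform(0, 40, 200)
        coarse = spatial_entropy(x, y, cell_size_m=20.0)
        fine = spatial_entropy(x, y, cell_size_m=10.0)
        assert fine >= coarse - 1e-12


class TestDistanceFromShore:
    def test_circle_centre_gives_radius(self):
        lake = Lake(polygon=ellipse_polygon(100.0, 100.0, n_vertices=720), lat=52.0, lon=13.0)
        assert lake.distance_from_shore(0.0, 0.0) == pytest.approx(100.0, abs=0.1)

    def test_boundary_point_zero(self):
        lake = Lake(polygon=ellipse_polygon(100.0, 100.0), lat=52.0, lon=13.0)
        bx, by = lake.polygon.exterior.coords[0]
        assert lake.distance_from_shore(bx, by) == pytest.approx(0.0, abs=1e-9)

    def test_square_lake_interior_point(self):
        from shapely.geometry import Polygon

        square = Lake(Polygon([(0, 0), (2, 0), (2, 2), (0, 2)]), lat=52.0, lon=13.0)
        assert square.distance_from_shore(1.0, 0.25) == pytest.approx(0.25)

    def test_outside_point_rejected(self):
        lake = Lake(polygon=ellipse_polygon(10.0, 10.0), lat=52.0, lon=13.0)
        with pytest.raises(ValueError, match="outside"):
            lake.distance_from_shore(50.0, 0.0)

    def test_matches_dense_boundary_sampling(self):
        lake = Lake(polygon=ellipse_polygon(80.0, 50.0, n_vertices=40), lat=52.0, lon=13.0)
        bpts = [
            lake.polygon.exterior.interpolate(f, normalized=True)
            for f in np.linspace(0, 1, 20000)
        ]
        bx = np.array([p.x for p in bpts])
        by = np.array([p.y for p in bpts])
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = rng.uniform(-30, 30), rng.uniform(-20, 20)
            brute = np.hypot(bx - x, by - y).min()
            assert lake.distance_from_shore(x, y) == pytest.approx(brute, abs=0.05)


class TestSpeed:
    def _traj(self, xs):
        from shoalnet.preprocess import TrajectorySet

        bins = pd.date_range("2021-01-01", periods=len(xs), freq="15s")
        x = np.array([[np.nan if v is None else v] for v in xs], dtype=float)
        valid = np.isfinite(x)
        zeros = np.where(valid, 0.0, np.nan)
        return TrajectorySet(
            bins=bins, fish_ids=np.array([0]), x=x, y=zeros.copy(),
            depth=zeros.copy(), temp=zeros.copy(), valid=valid,
        )

    def test_stationary_zero(self):
        v = speed_series(self._traj([4.0] * 5))
        assert np.allclose(v[1:, 0], 0.0)

    def test_half_metre_per_second(self):
        v = speed_series(self._traj([0.0, 7.5, 15.0]))
        assert np.allclose(v[1:, 0], 0.5)

    def test_no_speed_spans_gap(self):
        v = speed_series(self._traj([0.0, None, 15.0]))
        assert np.isnan(v[1, 0]) and np.isnan(v[2, 0])
        assert np.isnan(v[0, 0])


class TestDyadIndicators:
    def _calendar(self, n_bins, start="2021-01-01"):
        from shoalnet.preprocess import DielCalendar

        bins = pd.date_range(start, periods=n_bins, freq="15s")
        events = pd.DataFrame(
            {
                "date": [pd.Timestamp(start)],
                "sunrise": [pd.Timestamp(start)],
                "sunset": [bins[-1] + pd.Timedelta(days=1)],
            }
        )
        return DielCalendar(bins=bins, is_day=np.ones(n_bins, bool), events=events)

    def test_contact_every_detected_bin_gives_p_one(self):
        from shoalnet.contacts import events_table

        d = make_distance_set({(0, 1): [5.0] * 40})
        cal = self._calendar(40)
        ev = events_table(d, cal)
        dy = dyad_indicators(ev, d, cal)
        assert dy["p"].iloc[0] == 1.0

    def test_no_events_gives_p_zero_taus_undefined(self):
        d = make_distance_set({(0, 1): [50.0] * 40})
        cal = self._calendar(40)
        dy = dyad_indicators(pd.DataFrame(), d, cal)
        assert dy["p"].iloc[0] == 0.0
        assert np.isnan(dy["tau_plus_s"].iloc[0]) and np.isnan(dy["tau_minus_s"].iloc[0])

    def test_mean_duration_and_gap(self):
        from shoalnet.contacts import events_table

        # 60 s event, 10 min gap, 120 s event
        series = [5.0] * 4 + [50.0] * 40 + [5.0] * 8 + [50.0] * 4
        d = make_distance_set({(0, 1): series})
        cal = self._calendar(len(series))
        ev = events_table(d, cal)
        dy = dyad_indicators(ev, d, cal)
        assert dy["tau_plus_s"].iloc[0] == pytest.approx(90.0)
        assert dy["tau_minus_s"].iloc[0] == pytest.approx(600.0)

    def test_population_p_equals_pooled_ratio(self, tiny_bundle):
        dy = tiny_bundle["dyad_indicators"]
        dset = tiny_bundle["distances"]
        events = tiny_bundle["events"]
        cal = tiny_bundle["calendar"]
        from shoalnet.preprocess import MISSING

        in_event = np.zeros(dset.dist.shape, dtype=bool)
        col = {p: j for j, p in enumerate(dset.pairs)}
        for r in events.itertuples(index=False):
            in_event[r.first_bin : r.last_bin + 1, col[(r.pair_a, r.pair_b)]] = True
        detected = dset.status != MISSING
        pooled = in_event[detected].sum() / detected.sum()
        weighted = (dy["p"] * dy["n_detected_bins"]).sum() / dy["n_detected_bins"].sum()
        assert weighted == pytest.approx(pooled, rel=1e-9)

    def test_population_average_drops_undefined(self):
        df = pd.DataFrame(
            {
                "solar_day": ["d1"] * 3,
                "period": ["day"] * 3,
                "tau_plus_s": [60.0, np.nan, 120.0],
            }
        )
        out = population_average(df, ["tau_plus_s"])
        assert out["tau_plus_s"].iloc[0] == pytest.approx(90.0)


class TestEndToEndIndicators:
    def test_daily_indicator_invariants(self, tiny_bundle):
        daily = tiny_bundle["daily_indicators"]
        assert len(daily) > 0
        assert (daily["S"] >= 0).all()
        assert (daily["S"] <= np.log(daily["n_bins"]) + 1e-9).all()
        assert (daily["d"] >= 0).all()
        assert (daily["h"] >= 0).all()
        assert (daily["v"].dropna() >= 0).all()
        assert set(daily["period"]) == {"day", "night"}

    def test_dyad_invariants(self, tiny_bundle):
        dy = tiny_bundle["dyad_indicators"]
        assert dy["p"].between(0, 1).all()
        defined = dy["tau_plus_s"].dropna()
        assert (defined >= 30).all()
        gaps = dy["tau_minus_s"].dropna()
        assert (gaps >= 300).all()
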