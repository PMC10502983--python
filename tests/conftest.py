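import numpy as np
import pandas as pd
import pytest

from shoalnet.config import BIN_SECONDS, RunConfig, SimulationConfig
from shoalnet.lake import Lake, ellipse_polygon
from shoalnet.preprocess import MEASURED, MISSING, DistanceSet


@pytest.fixture(scope="session")
def small_lake() -> Lake:
    return Lake(polygon=ellipse_polygon(150.0, 120.0, n_vertices=72), lat=52.995, lon=13.582)


@pytest.fixture(scope="session")
def tiny_sim_cfg(small_lake):
    return SimulationConfig(
        n_fish=6,
        duration_days=2,
        burst_interval_s=15,
        lake=small_lake,
        n_groups=2,
        rng_seed=7,
        start="2021-06-01T00:00:00",
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_sim_cfg):
    from shoalnet.simulate import simulate_population

    return simulate_population(tiny_sim_cfg)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_sim_cfg, tmp_path_factory):
    from shoalnet.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("bundle")
    return run_pipeline(RunConfig(output_dir=str(out), seed=11), sim_cfg=tiny_sim_cfg)


def make_distance_set(dist_by_pair: dict, start="2021-01-01") -> DistanceSet:
    """Build a DistanceSet from {(a, b): [distances...]} with NaN = missing."""
    pairs = list(dist_by_pair)
    arr = np.column_stack([np.asarray(v, dtype=np.float32) for v in dist_by_pair.values()])
    status = np.where(np.isnan(arr), MISSING, MEASURED).astype(np.int8)
    bins = pd.date_range(start, periods=arr.shape[0], freq=f"{BIN_SECONDS}s")
    return DistanceSet(bins=bins, pairs=pairs, dist=arr, status=status)
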