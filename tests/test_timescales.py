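"""Window ladder, excess networks, community detection, memory timescale."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from shoalnet.networks import aggregate
from shoalnet.timescales import (
    DEFAULT_LADDER,
    detect_communities,
    excess_network,
    memory_timescale,
    split_ladder,
)

MONTH = (pd.Timestamp("2021-06-01"), pd.Timestamp("2021-06-29"))


class TestSplitLadder:
    def test_two_week_level_has_two_slices(self):
        assert len(split_ladder(MONTH)[336]) == 2

    def test_one_hour_level_has_672_slices(self):
        assert len(split_ladder(MONTH)[1]) == 672

    def test_partition_identity_every_level(self):
        for dur, windows in split_ladder(MONTH).items():
            assert len(windows) * dur == 672
            assert windows[0][0] == MONTH[0]
            assert windows[-1][1] == MONTH[1]
            for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
                assert e0 == s1

    def test_non_672h_window_rejected(self):
        with pytest.raises(ValueError, match="672"):
            split_ladder((MONTH[0], MONTH[0] + pd.Timedelta(days=30)))

    def test_non_divisor_duration_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            split_ladder(MONTH, ladder_hours=(5,))


def _graph(edges, window=MONTH, provenance="real"):
    g = nx.Graph(window=window, period=None, provenance=provenance)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


class TestExcessNetwork:
    def test_subtraction(self):
        ex = excess_network(_graph([(0, 1, 5)]), _graph([(0, 1, 2)]))
        assert ex[0][1]["weight"] == 3

    def test_clamped_at_zero(self):
        ex = excess_network(_graph([(0, 1, 2)]), _graph([(0, 1, 5)]))
        assert not ex.has_edge(0, 1)

    def test_empty_null_gives_real(self):
        ex = excess_network(_graph([(0, 1, 4), (1, 2, 1)]), _graph([]))
        assert ex[0][1]["weight"] == 4 and ex[1][2]["weight"] == 1

    def test_mismatched_windows_rejected(self):
        other = (MONTH[0] + pd.Timedelta(days=28), MONTH[1] + pd.Timedelta(days=28))
        with pytest.raises(ValueError, match="window"):
            excess_network(_graph([]), _graph([], window=other))


class TestDetectCommunities:
    def test_two_disjoint_triangles(self):
        g = _graph([(0, 1, 9), (1, 2, 9), (0, 2, 9), (3, 4, 9), (4, 5, 9), (3, 5, 9)])
        labels, n3 = detect_communities(g)
        assert n3 == 2
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5] != labels[0]

    def test_single_clique(self):
        g = _graph([(a, b, 5) for a in range(5) for b in range(a + 1, 5)])
        _, n3 = detect_communities(g)
        assert n3 == 1

    def test_ring_of_four_weak_triangles(self):
        edges = []
        for k in range(4):
            base = 3 * k
            edges += [(base, base + 1, 50), (base + 1, base + 2, 50), (base, base + 2, 50)]
            edges.append((base + 2, (base + 3) % 12, 1))  # weak ring link
        g = _graph(edges)
        _, n3 = detect_communities(g)
        assert n3 == 4
        # independent oracle on the same toy graph: modularity-based detection
        import igraph

        ig = igraph.Graph(
            n=12, edges=[(a, b) for a, b, _ in edges]
        )
        oracle = ig.community_multilevel(weights=[w for _, _, w in edges])
        assert len([c for c in oracle.sizes() if c >= 3]) == 4

    def test_empty_edge_set_zero_communities(self):
        g = _graph([])
        g.add_nodes_from(range(6))
        labels, n3 = detect_communities(g)
        assert n3 == 0
        assert len(set(labels.values())) == 6  # isolated nodes are singletons

    def test_isolated_nodes_never_counted(self):
        g = _graph([(0, 1, 9), (1, 2, 9), (0, 2, 9)])
        g.add_nodes_from([10, 11, 12, 13])
        _, n3 = detect_communities(g)
        assert n3 == 1

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(4)
        edges = [
            (int(a), int(b), int(w))
            for a, b, w in zip(
                rng.integers(0, 15, 60), rng.integers(0, 15, 60), rng.integers(1, 9, 60)
            )
            if a != b
        ]
        g = _graph(list({(min(a, b), max(a, b)): (a, b, w) for a, b, w in edges}.values()))
        first = detect_communities(g, seed=3)
        for _ in range(3):
            assert detect_communities(g, seed=3) == first


class TestMemoryTimescale:
    def _curve(self, counts):
        return pd.DataFrame(
            {"duration_h": list(DEFAULT_LADDER), "mean_communities": counts}
        )

    def test_peak_at_two_weeks(self):
        counts = [1.0, 3.2, 2.8, 2.5, 2.0, 1.8, 1.5, 1.2, 1.1, 1.0]
        assert memory_timescale(self._curve(counts)) == 336

    def test_monotone_decreasing_gives_shortest(self):
        counts = [3.0, 2.9, 2.5, 2.2, 2.0, 1.7, 1.4, 1.2, 1.1, 1.05][::-1]
        assert memory_timescale(self._curve(counts)) == 1

    def test_tie_breaks_to_longest(self):
        counts = [1.0, 2.0, 3.0, 3.0, 3.0, 2.0, 1.0, 1.0, 1.0, 1.0]
        assert memory_timescale(self._curve(counts)) == 168

    def test_all_zero_undefined(self):
        assert np.isnan(memory_timescale(self._curve([0.0] * 10)))


class TestCurveOnSyntheticMonth:
    @pytest.fixture(scope="class")
    def curve(self):
        from shoalnet.experiments import STRONG_ATTRACTION, _study_config
        from shoalnet.config import RunConfig
        from shoalnet.pipeline import infer_contacts, prepare, shuffled_contacts
        from shoalnet.simulate import simulate_population
        from shoalnet.timescales import timescale_curve

        sim = _study_config(seed=0, attraction=STRONG_ATTRACTION, days=28, tau_h=48.0)
        run = RunConfig(seed=1)
        fixes, _ = simulate_population(sim)
        traj, dset, cal = prepare(fixes, sim.lake, run)
        events = infer_contacts(dset, cal, run)
        sh_events, _ = shuffled_contacts(traj, cal, run)
        window = (traj.bins[0], traj.bins[0] + pd.Timedelta(hours=672))
        return timescale_curve(events, sh_events, [int(f) for f in traj.fish_ids], window)

    def test_curve_structure(self, curve):
        assert list(curve["duration_h"]) == list(DEFAULT_LADDER)
        assert (curve["n_slices"] * curve["duration_h"] == 672).all()
        assert (curve["realized_link_pct"] <= 100).all()

    def test_full_month_aggregation_mixes_toward_one_community(self, curve):
        assert curve.loc[curve["duration_h"] == 672, "mean_communities"].iloc[0] <= 2

    def test_hour_scale_realizes_fewest_links(self, curve):
        pct = curve.set_index("duration_h")["realized_link_pct"]
        assert pct.loc[1] == pct.min()
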