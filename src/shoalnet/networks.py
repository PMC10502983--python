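"""Aggregation of contact events into weighted networks, and clustering.

A network aggregates the contact events of one time window (half-open on
the event start instant) and optionally one diel period: edge weight is
the number of events of the pair, with total contact seconds carried
alongside.  The average local clustering coefficient is computed on the
binarized graph with the convention that nodes of degree < 2 contribute
zero to the average.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd


def aggregate(
    events: pd.DataFrame,
    nodes,
    window: tuple[pd.Timestamp, pd.Timestamp],
    period: str | None = None,
    provenance: str = "real",
) -> nx.Graph:
    """Weighted undirected network over ``nodes`` for one window x period.

    An event belongs to the window containing its start instant
    (half-open [start, end)); ``period`` of None aggregates day and night
    together.
    """
    start, end = window
    if not end > start:
        raise ValueError("empty aggregation window")
    g = nx.Graph(window=(start, end), period=period, provenance=provenance)
    g.add_nodes_from(int(n) for n in nodes)
    if len(events):
        m = (events["start"] >= start) & (events["start"] < end)
        if period is not None:
            m &= events["period"] == period
        sel = events[m]
        if len(sel):
            agg = sel.groupby(["pair_a", "pair_b"]).agg(
                weight=("duration_s", "size"), seconds=("duration_s", "sum")
            )
            for (a, b), row in agg.iterrows():
                g.add_edge(int(a), int(b), weight=int(row["weight"]), seconds=float(row["seconds"]))
    return g


def avg_local_clustering(g: nx.Graph, binarize: bool = True, count_zeros: bool = True) -> float:
    """Mean over nodes of (triangles through node) / (degree choose 2).

    Bounded in [0, 1]; nodes of degree < 2 contribute 0 when
    ``count_zeros`` (the default) and are excluded otherwise.  Weighted
    clustering is deliberately not used: edges are binarized.
    """
    if g.number_of_nodes() < 3:
        return float("nan")
    h = nx.Graph(g.edges()) if binarize else g
    h.add_nodes_from(g.nodes())
    local = nx.clustering(h)
    vals = list(local.values())
    if not count_zeros:
        vals = [c for n, c in local.items() if h.degree(n) >= 2]
        if not vals:
            return float("nan")
    return float(np.mean(vals))
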