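"""Plain-text formats and provenance for the pipeline.

All tabular outputs are CSV with a sidecar ``.schema.json`` describing
columns and dtypes; timestamps are ISO-8601 UTC.  A machine-readable run
manifest records the configuration, seeds, library versions, row counts
and content hashes of every written file, so identical seeds yield an
identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from datetime import datetime, timezone

import networkx as nx
import pandas as pd

logger = logging.getLogger("shoalnet")

FIX_COLUMNS = ["fish_id", "timestamp", "x_m", "y_m", "depth_m", "temp_c"]


def read_fixes(path: str) -> pd.DataFrame:
    """Read and validate a fix CSV (fish_id, timestamp, x_m, y_m, depth_m,
    optional temp_c).  Bad rows (unparseable timestamps, non-finite
    coordinates, negative depth) are dropped and counted in the log."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty fix table: {path}")
    required = set(FIX_COLUMNS) - {"temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fix table missing columns: {sorted(missing)}")
    n0 = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True).dt.tz_localize(None)
    bad = df["timestamp"].isna()
    for col in ("x_m", "y_m", "depth_m"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad |= ~df[col].notna()
    bad |= df["depth_m"] < 0
    if bad.any():
        logger.warning("dropped %d/%d bad fix rows from %s", int(bad.sum()), n0, path)
    df = df[~bad].sort_values(["fish_id", "timestamp"], kind="mergesort", ignore_index=True)
    if df.empty:
        raise ValueError(f"no valid fixes in {path}")
    return df


def _schema(df: pd.DataFrame) -> dict:
    return {c: str(t) for c, t in df.dtypes.items()}


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)
    with open(path + ".schema.json", "w") as fh:
        json.dump({"columns": _schema(df), "n_rows": len(df)}, fh, indent=1)


def write_edge_lists(networks: list[nx.Graph], path: str) -> None:
    """Serialize aggregated networks as one weighted-edge CSV."""
    rows = []
    for g in networks:
        w0, w1 = g.graph["window"]
        for a, b, d in sorted(g.edges(data=True)):
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "weight_count": d["weight"],
                    "weight_seconds": d.get("seconds", float("nan")),
                    "window_start": w0.isoformat(),
                    "window_end": w1.isoformat(),
                    "period": g.graph.get("period") or "both",
                    "provenance": g.graph.get("provenance", "real"),
                }
            )
    write_table(pd.DataFrame(rows), path)


def read_edge_lists(path: str, nodes=()) -> list[nx.Graph]:
    """Re-read networks written by :func:`write_edge_lists` bit-identically
    (same windows, weights and provenance)."""
    df = pd.read_csv(path)
    out = []
    if df.empty:
        return out
    for (w0, w1, period, prov), sub in df.groupby(
        ["window_start", "window_end", "period", "provenance"], sort=True
    ):
        g = nx.Graph(
            window=(pd.Timestamp(w0), pd.Timestamp(w1)),
            period=None if period == "both" else period,
            provenance=prov,
        )
        g.add_nodes_from(int(n) for n in nodes)
        for row in sub.itertuples(index=False):
            g.add_edge(
                int(row.a), int(row.b), weight=int(row.weight_count), seconds=float(row.weight_seconds)
            )
        out.append(g)
    return out


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str, config: dict, seeds: dict, counts: dict) -> dict:
    """Write run manifest (config, seeds, versions, row counts, file
    hashes) and return it; the manifest hash is deterministic for fixed
    seeds and inputs."""
    import numpy, scipy, networkx as nxmod, igraph

    files = sorted(
        f for f in os.listdir(out_dir) if f.endswith((".csv", ".json")) and f != "manifest.json"
    )
    manifest = {
        "config": config,
        "seeds": seeds,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "networkx": nxmod.__version__,
            "igraph": igraph.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": counts,
        "files": {f: file_sha256(os.path.join(out_dir, f)) for f in files},
    }
    hashed_config = {
        k: v
        for k, v in config.items()
        if k not in ("output_dir", "fixes_path", "lake_path", "diel_override_path")
    }
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(
            {"config": hashed_config, **{k: manifest[k] for k in ("seeds", "row_counts", "files")}},
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()
    manifest["written_utc"] = datetime.now(timezone.utc).isoformat()
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
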