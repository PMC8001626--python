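"""Readers and writers for the pipeline's file formats.

Tables travel as TSV (rows = taxa/parameters, columns = samples, first
column the row id), graphs as GraphML with an edge-list TSV mirror, reports
as JSON. All writers are deterministic: no timestamps, sorted JSON keys,
stable row order.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .preprocessing import NormalizedTable

__all__ = [
    "read_counts",
    "write_table",
    "read_table",
    "read_similarity",
    "read_groups",
    "write_normalized",
    "read_normalized",
    "write_graphml",
    "read_graphml",
    "write_edge_list",
    "write_assignment",
    "read_assignment",
]


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="id")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_counts(path) -> pd.DataFrame:
    counts = read_table(path)
    if (counts < 0).any().any():
        raise ValueError("count table contains negative values")
    return counts.astype(int)


def read_similarity(path) -> pd.DataFrame:
    sim = read_table(path)
    sim.columns = [str(c) for c in sim.columns]
    sim.index = [str(i) for i in sim.index]
    return sim


def read_groups(path) -> dict[str, str]:
    """Two-column TSV: sample id, group name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group file needs two columns: sample, group")
    sample_col, group_col = df.columns[:2]
    return dict(zip(df[sample_col], df[group_col]))


def write_normalized(norm: NormalizedTable, path) -> None:
    out = norm.values.copy()
    out.insert(0, "is_env", norm.is_env.astype(int).to_numpy())
    out.to_csv(path, sep="\t", index_label="id")


def read_normalized(path) -> NormalizedTable:
    df = read_table(path)
    if "is_env" not in df.columns:
        raise ValueError("normalized table lacks the is_env column")
    is_env = df["is_env"].astype(bool)
    return NormalizedTable(values=df.drop(columns="is_env"), is_env=is_env)


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path, named_key_ids=True)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, **{k: data[k] for k in sorted(data)}}
        for u, v, data in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_assignment(assignment, path) -> None:
    rows = sorted(assignment.member_map.items())
    pd.DataFrame(rows, columns=["member", "nsc"]).to_csv(path, sep="\t", index=False)


def read_assignment(path):
    from .clustering import NSCAssignment

    df = pd.read_csv(path, sep="\t", dtype=str)
    member_map = dict(zip(df["member"], df["nsc"]))
    return NSCAssignment(
        member_map=member_map, nsc_ids=sorted(set(member_map.values()))
    )


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
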