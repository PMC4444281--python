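"""Plain-text readers and writers for the pipeline's artifacts.

Everything is TSV or JSON so runs are auditable and diffable: expression
matrices and edge lists as TSV, networks additionally as GraphML (with the
threshold tau stored as a graph attribute), partitions as two-column TSV and
reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "write_edge_list", "read_edge_list",
    "write_graphml",
    "write_partition", "read_partition",
    "write_json", "read_json",
]


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"node_a": str(u), "node_b": str(v), "r": data.get("r", "")}
        for u, v, data in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "r"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        attrs = {}
        if "r" in df.columns and pd.notna(row.r) and row.r != "":
            attrs["r"] = float(row.r)
        g.add_edge(row.node_a, row.node_b, **attrs)
    return g


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def write_partition(part, path, letters: dict | None = None) -> None:
    assignment = part.community_of_node if hasattr(part, "community_of_node") else part
    rows = [
        {"node": str(v), "community": letters[c] if letters else c}
        for v, c in sorted(assignment.items(), key=lambda kv: str(kv[0]))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_partition(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"node": str, "community": str})
    return dict(zip(df["node"], df["community"]))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
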