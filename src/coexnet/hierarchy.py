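"""Concentric node degrees and the hub / VIP / high-hub categorisation.

For a node u, k0 is the ordinary degree and k1 is the first-level concentric
degree: the number of edges leaving u's immediate neighbourhood, i.e. edges
with one endpoint among u's neighbours (ring 1) and the other at shortest-path
distance two from u (ring 2). Edges inside ring 1 and edges back to u are not
counted.

Plotting k0 against k1 separates three biologically distinct roles:

* hubs — high k0 but not a top k1 (locally dominant connectors),
* VIPs — low k0 but top k1 (their few neighbours are themselves hubs),
* high-hubs — top k0 and top k1 (hub and VIP character at once).

Cut-offs are quantiles of the attained (distinct) k0 and k1 values, so the
thresholds are always values that occur in the network.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

logger = logging.getLogger("coexnet")

__all__ = ["concentric_degrees", "classify_nodes", "hierarchy_table", "CATEGORIES"]

CATEGORIES = ("high-hub", "hub", "VIP", "other")
_CAT_RANK = {c: i for i, c in enumerate(CATEGORIES)}


def concentric_degrees(net: nx.Graph, node) -> tuple[int, int]:
    """(k0, k1) for one node: degree, and ring1→ring2 edge count."""
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    ring1 = set(net[node])
    k0 = len(ring1)
    ring2: set = set()
    for v in ring1:
        ring2.update(net[v])
    ring2 -= ring1
    ring2.discard(node)
    k1 = sum(len(set(net[v]) & ring2) for v in ring1)
    return k0, k1


def _nearest_rank(distinct_sorted: list[int], q: float) -> int:
    """Inclusive nearest-rank quantile over distinct attained values."""
    idx = max(1, math.ceil(q * len(distinct_sorted)))
    return distinct_sorted[idx - 1]


def classify_nodes(
    net: nx.Graph, hub_quantile: float = 0.9, vip_k0_quantile: float = 0.5
) -> pd.DataFrame:
    """Categorise every node from its (k0, k1) pair.

    With Tk0 / Tk1 the ``hub_quantile``-quantiles of the attained k0 / k1
    values and Lk0 the ``vip_k0_quantile``-quantile of k0:

    * high-hub: k0 >= Tk0 and k1 >= Tk1
    * hub:      k0 >= Tk0 and k1 <  Tk1
    * VIP:      k0 <= Lk0 and k1 >= Tk1
    * other:    everything else.

    If the network attains a single k0 or a single k1 value the quantiles
    collapse and every node is "other" (logged warning). Rows are sorted by
    (category, -k1, -k0).
    """
    if not (0 < hub_quantile < 1) or not (0 < vip_k0_quantile < 1):
        raise ValueError("quantiles must be in (0, 1)")
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    rows = [(node, *concentric_degrees(net, node)) for node in net.nodes()]
    k0s = sorted({k0 for _, k0, _ in rows})
    k1s = sorted({k1 for _, _, k1 in rows})

    if len(k0s) == 1 or len(k1s) == 1:
        logger.warning("classify_nodes: degenerate k0/k1 distribution; all nodes 'other'")
        cats = {node: "other" for node, _, _ in rows}
    else:
        tk0 = _nearest_rank(k0s, hub_quantile)
        tk1 = _nearest_rank(k1s, hub_quantile)
        lk0 = _nearest_rank(k0s, vip_k0_quantile)
        cats = {}
        for node, k0, k1 in rows:
            if k0 >= tk0 and k1 >= tk1:
                cats[node] = "high-hub"
            elif k0 >= tk0:
                cats[node] = "hub"
            elif k0 <= lk0 and k1 >= tk1:
                cats[node] = "VIP"
            else:
                cats[node] = "other"
    df = pd.DataFrame(
        [(node, k0, k1, cats[node]) for node, k0, k1 in rows],
        columns=["node", "k0", "k1", "category"],
    )
    df["_rank"] = df["category"].map(_CAT_RANK)
    df = (
        df.sort_values(["_rank", "k1", "k0"], ascending=[True, False, False])
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return df


def hierarchy_table(net: nx.Graph, hub_quantile: float = 0.9,
                    vip_k0_quantile: float = 0.5) -> pd.DataFrame:
    """One (node, k0, k1, category) row per node — the k0-vs-k1 scatter data."""
    return classify_nodes(net, hub_quantile, vip_k0_quantile)
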