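"""Community detection, modularity, partition comparison and coarse-graining.

Communities are found by multilevel (Louvain-style) greedy modularity
optimisation at resolution 1 on the unweighted graph; the best of several
seeded restarts is kept. Modularity is the Newman–Girvan quality

    Q = sum_c [ e_c / L  -  (d_c / 2L)^2 ]

with e_c the number of edges inside community c and d_c its total degree.
The coarse-grained community structure (CGCS) contracts every community to a
single node; edge counts inside and between communities become node/edge
weights, and each inter-community weight is also expressed as a fraction of
the total edge count (the mixing matrix of the partition).
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

logger = logging.getLogger("coexnet")

__all__ = [
    "Partition",
    "CoarseNetwork",
    "modularity",
    "detect_communities",
    "compare_partitions",
    "coarse_grain",
    "top_communities",
    "community_letters",
]


@dataclass
class Partition:
    """Node -> community assignment (0-based, contiguous) with its modularity."""

    community_of_node: dict
    q: float
    n_communities: int

    def labels_for(self, nodes) -> list[int]:
        return [self.community_of_node[v] for v in nodes]

    def members(self) -> list[set]:
        out: list[set] = [set() for _ in range(self.n_communities)]
        for v, c in self.community_of_node.items():
            out[c].add(v)
        return out


def modularity(net: nx.Graph, assignment) -> float:
    """Newman–Girvan modularity of an assignment (dict node -> community)."""
    missing = set(net.nodes()) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses {len(missing)} nodes, e.g. {sorted(map(str, missing))[:3]}")
    L = net.number_of_edges()
    if L == 0:
        logger.warning("modularity: graph has no edges; Q defined as 0")
        return 0.0
    intra: dict = {}
    deg: dict = {}
    for u, v in net.edges():
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0) + 1
    for v, d in net.degree():
        c = assignment[v]
        deg[c] = deg.get(c, 0) + d
    q = 0.0
    for c in set(assignment[v] for v in net.nodes()):
        q += intra.get(c, 0) / L - (deg.get(c, 0) / (2.0 * L)) ** 2
    return q


def _normalise(net: nx.Graph, membership: dict) -> Partition:
    """Relabel communities contiguously, largest first (ties by node id)."""
    groups: dict = {}
    for v, c in membership.items():
        groups.setdefault(c, set()).add(v)
    ordered = sorted(
        groups.values(), key=lambda s: (-len(s), min(str(v) for v in s))
    )
    out = {v: i for i, s in enumerate(ordered) for v in s}
    return Partition(out, modularity(net, out), len(ordered))


def detect_communities(net: nx.Graph, seed: int = 0, n_restarts: int = 10) -> Partition:
    """Multilevel modularity optimisation, best of ``n_restarts`` seeded runs.

    Communities in the returned partition are indexed 0, 1, ... in descending
    size. The reported q always equals :func:`modularity` recomputed on the
    returned assignment.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    if n == 1 or net.number_of_edges() == 0:
        return _normalise(net, {v: 0 for v in net.nodes()})

    nodes = sorted(net.nodes(), key=str)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=n, edges=[(index[u], index[v]) for u, v in net.edges()])
    ss = np.random.SeedSequence(seed)
    best: Partition | None = None
    for child in ss.spawn(n_restarts):
        _random.seed(int(child.generate_state(1)[0] % (2**31)))  # igraph uses Python's RNG
        vc = g.community_multilevel()
        part = _normalise(net, {nodes[i]: c for i, c in enumerate(vc.membership)})
        if best is None or part.q > best.q + 1e-15:
            best = part
    return best


def _as_assignment(p) -> dict:
    return p.community_of_node if isinstance(p, Partition) else dict(p)


def compare_partitions(a, b) -> tuple[float, float]:
    """(ARI, NMI) between two partitions of the same node set."""
    da, db = _as_assignment(a), _as_assignment(b)
    if set(da) != set(db):
        diff = sorted(map(str, set(da) ^ set(db)))
        raise ValueError(f"partitions cover different nodes; symmetric difference {diff[:5]}")
    nodes = sorted(da, key=str)
    la = [da[v] for v in nodes]
    lb = [db[v] for v in nodes]
    return (
        float(adjusted_rand_score(la, lb)),
        float(normalized_mutual_info_score(la, lb)),
    )


def community_letters(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... labels for communities in size order."""
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = chr(ord("A") + j % 26) + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


@dataclass
class CoarseNetwork:
    """Contraction of a network onto its communities (mixing matrix)."""

    sizes: dict            # community -> node count
    intra_edges: dict      # community -> edges inside it
    inter_edges: dict      # frozenset({a, b}) -> edges between a and b
    total_edges: int

    @property
    def weight_fraction(self) -> dict:
        if self.total_edges == 0:
            return {k: 0.0 for k in self.inter_edges}
        return {k: v / self.total_edges for k, v in self.inter_edges.items()}

    @property
    def communities(self) -> list[tuple[int, int]]:
        return sorted(self.sizes.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for c, size in self.sizes.items():
            g.add_node(c, size=size, intra_edges=self.intra_edges.get(c, 0))
        for pair, w in self.inter_edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, weight=w, fraction=self.weight_fraction[pair])
        return g

    def to_dict(self) -> dict:
        letters = community_letters(len(self.sizes))
        order = [c for c, _ in self.communities]
        letter_of = {c: letters[i] for i, c in enumerate(order)}
        return {
            "communities": [
                {"index": c, "letter": letter_of[c], "size": s,
                 "intra_edges": self.intra_edges.get(c, 0)}
                for c, s in self.communities
            ],
            "inter": [
                {"a": letter_of[min(p)], "b": letter_of[max(p)], "edges": w,
                 "fraction": self.weight_fraction[p]}
                for p, w in sorted(self.inter_edges.items(),
                                   key=lambda kv: (-kv[1], sorted(kv[0])))
            ],
            "total_edges": self.total_edges,
        }


def coarse_grain(net: nx.Graph, part) -> CoarseNetwork:
    """Contract every community to one node, counting intra/inter edges."""
    assignment = _as_assignment(part)
    missing = set(net.nodes()) - set(assignment)
    if missing:
        raise ValueError(f"partition misses {len(missing)} network nodes")
    sizes: dict = {}
    for v in net.nodes():
        c = assignment[v]
        sizes[c] = sizes.get(c, 0) + 1
    intra: dict = {}
    inter: dict = {}
    for u, v in net.edges():
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0) + 1
        else:
            key = frozenset((cu, cv))
            inter[key] = inter.get(key, 0) + 1
    return CoarseNetwork(sizes, intra, inter, net.number_of_edges())


def top_communities(coarse: CoarseNetwork, k: int, keep=()) -> CoarseNetwork:
    """Restrict the coarse network to the k largest communities (ties by
    index) plus an optional keep-list of extra community indices."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = [c for c, _ in coarse.communities]
    if k > len(order):
        logger.warning("top_communities: k=%d exceeds %d communities; keeping all",
                       k, len(order))
        k = len(order)
    kept = set(order[:k]) | (set(keep) & set(order))
    return CoarseNetwork(
        sizes={c: s for c, s in coarse.sizes.items() if c in kept},
        intra_edges={c: e for c, e in coarse.intra_edges.items() if c in kept},
        inter_edges={p: w for p, w in coarse.inter_edges.items() if p <= kept},
        total_edges=coarse.total_edges,
    )
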