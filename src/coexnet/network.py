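"""Coexpression-network construction: Pearson correlation, absolute-value
thresholding, data-driven threshold selection, and connectivity diagnostics.

A gene coexpression network (GCN) has genes as nodes and an edge wherever a
pair of genes shows a high absolute Pearson correlation across one group's
samples. The link-strength threshold tau is chosen so that (a) essentially
all connectable nodes fall in the major (giant) component and (b) the
community structure is stable under slight changes of tau — quantified here
as the adjusted Rand index between partitions at neighbouring thresholds.
After thresholding, the network is restricted to its largest connected
component. Connectivity is the mean degree k = 2L/N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("coexnet")

__all__ = [
    "CorrelationMatrix",
    "EmptyNetworkError",
    "ThresholdSelectionError",
    "correlation_matrix",
    "build_network",
    "select_threshold",
    "connectivity",
    "degree_distribution",
]


class EmptyNetworkError(ValueError):
    """Raised when a threshold leaves no edges at all."""

    def __init__(self, tau: float, max_abs_r: float):
        self.tau = tau
        self.max_abs_r = max_abs_r
        super().__init__(
            f"threshold {tau} yields zero edges (max |r| = {max_abs_r:.6f})"
        )


class ThresholdSelectionError(ValueError):
    """No grid threshold satisfies the component + stability criteria."""

    def __init__(self, report: pd.DataFrame):
        self.report = report
        super().__init__(
            "no threshold in the grid satisfies both the giant-component and "
            "stability criteria; see .report"
        )


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson correlations with per-pair sample counts."""

    genes: list[str]
    r: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.genes)
        if self.r.shape != (m, m):
            raise ValueError("r must be square over the gene list")
        if not np.allclose(self.r, self.r.T, equal_nan=True):
            raise ValueError("r must be symmetric")

    def max_abs_offdiag(self) -> float:
        a = np.abs(self.r.copy())
        np.fill_diagonal(a, np.nan)
        return float(np.nanmax(a)) if a.size and not np.isnan(a).all() else 0.0


def correlation_matrix(matrix, group: str, min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation over one group's samples.

    Genes with zero variance within the group are excluded (logged); pairs
    with fewer than ``min_pairs`` jointly finite samples get r = NaN, which
    every threshold treats as an absent edge.
    """
    sub = matrix.group_values(group)
    if sub.shape[1] < 3:
        raise ValueError(f"group {group!r} has {sub.shape[1]} samples; need >= 3")
    x = sub.to_numpy(dtype=float)
    finite = np.isfinite(x)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(x, axis=1)
        n_finite = finite.sum(axis=1)
    keep = (sd > 0) & (n_finite >= 2)
    if not keep.all():
        logger.info(
            "correlation_matrix[%s]: excluding %d constant/empty genes",
            group, int((~keep).sum()),
        )
    genes = [g for g, k in zip(sub.index, keep) if k]
    x = x[keep]
    finite = finite[keep]
    n_pairs = finite.astype(np.int64) @ finite.T

    if len(genes) == 1:
        r = np.ones((1, 1))
    elif finite.all():
        r = np.corrcoef(x)
    else:
        r = pd.DataFrame(x.T).corr(min_periods=min_pairs).to_numpy()
    r = np.clip(r, -1.0, 1.0)
    r[n_pairs < min_pairs] = np.nan
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes, r, n_pairs)


def _largest_component(g: nx.Graph) -> nx.Graph:
    comps = list(nx.connected_components(g))
    best_size = max(len(c) for c in comps)
    # tie-break: the component containing the smallest lexicographic node id
    best = min(
        (c for c in comps if len(c) == best_size),
        key=lambda c: min(str(v) for v in c),
    )
    return g.subgraph(best).copy()


def build_network(corr: CorrelationMatrix, tau: float) -> nx.Graph:
    """Threshold |r| >= tau into a simple undirected graph, then keep the
    largest connected component. The threshold is stored as ``G.graph['tau']``
    and each edge carries its signed correlation as attribute ``r``.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    a = np.abs(corr.r)
    np.fill_diagonal(a, 0.0)
    ii, jj = np.nonzero(np.triu(a >= tau, k=1))
    if len(ii) == 0:
        raise EmptyNetworkError(tau, corr.max_abs_offdiag())
    g = nx.Graph(tau=tau)
    genes = corr.genes
    g.add_edges_from(
        (genes[i], genes[j], {"r": float(corr.r[i, j])}) for i, j in zip(ii, jj)
    )
    n_with_edge = g.number_of_nodes()
    g = _largest_component(g)
    g.graph["tau"] = tau
    dropped = n_with_edge - g.number_of_nodes()
    if dropped:
        logger.info("build_network(tau=%.4g): dropped %d nodes outside the giant component",
                    tau, dropped)
    return g


def connectivity(net: nx.Graph) -> float:
    """Mean degree k = 2L/N."""
    n = net.number_of_nodes()
    if n < 1:
        raise ValueError("network has no nodes")
    return 2.0 * net.number_of_edges() / n


def degree_distribution(net: nx.Graph) -> pd.DataFrame:
    """Table of (degree, count, frequency); zero-count degrees omitted."""
    degs = np.array([d for _, d in net.degree()], dtype=int)
    vals, counts = np.unique(degs, return_counts=True)
    return pd.DataFrame(
        {"degree": vals, "count": counts, "frequency": counts / counts.sum()}
    )


def select_threshold(
    corr: CorrelationMatrix,
    tau_grid,
    stability_delta: float | None = None,
    min_component_frac: float = 0.8,
    stability_min: float = 0.8,
    seed: int = 0,
    n_restarts: int = 2,
):
    """Pick the largest threshold whose network is dominated by its giant
    component and whose community structure is stable to a small tau change.

    For every tau in the ascending grid the candidate network is built and
    partitioned (seeded Louvain); a tau qualifies when

    a. the largest component holds at least ``min_component_frac`` of the
       nodes that have any edge at that tau, and
    b. the adjusted Rand index between its partition and the partitions at
       tau ± ``stability_delta`` (computed on the shared nodes) is at least
       ``stability_min``.

    ``stability_delta`` defaults to the grid spacing, so neighbours are the
    adjacent grid points. Returns ``(tau, report)`` where the report lists
    N, L, giant-component fraction and neighbour ARIs per tau; if no tau
    qualifies a :class:`ThresholdSelectionError` carrying the report is
    raised.
    """
    from .community import compare_partitions, detect_communities

    grid = [float(t) for t in tau_grid]
    if not grid or any(not (0.0 < t < 1.0) for t in grid):
        raise ValueError("tau_grid must be non-empty and within (0, 1)")
    if sorted(grid) != grid:
        raise ValueError("tau_grid must be ascending")

    if stability_delta is None:
        eval_taus = list(grid)
        neighbours = {
            t: [grid[j] for j in (i - 1, i + 1) if 0 <= j < len(grid)]
            for i, t in enumerate(grid)
        }
    else:
        eval_taus = sorted(
            {round(t, 12) for t in grid}
            | {round(t + d, 12) for t in grid for d in (-stability_delta, stability_delta)
               if 0.0 < t + d < 1.0}
        )
        neighbours = {
            t: [round(t + d, 12) for d in (-stability_delta, stability_delta)
                if 0.0 < t + d < 1.0]
            for t in grid
        }

    nets: dict[float, nx.Graph | None] = {}
    parts: dict[float, dict] = {}
    rows = []
    a = np.abs(corr.r)
    np.fill_diagonal(a, 0.0)
    for t in eval_taus:
        try:
            net = build_network(corr, t)
        except EmptyNetworkError:
            nets[t] = None
            continue
        nets[t] = net
        n_with_edge = int(np.count_nonzero((np.nan_to_num(a) >= t).any(axis=1)))
        part = detect_communities(net, seed=seed, n_restarts=n_restarts)
        parts[t] = part
        rows.append(
            {
                "tau": t,
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "giant_frac": net.number_of_nodes() / n_with_edge,
            }
        )
    report = pd.DataFrame(rows)

    def _neighbour_ari(t: float) -> float:
        aris = []
        for u in neighbours[t]:
            if nets.get(u) is None:
                continue
            shared = set(nets[t]) & set(nets[u])
            if len(shared) < 2:
                aris.append(0.0)
                continue
            pa = {v: parts[t].community_of_node[v] for v in shared}
            pb = {v: parts[u].community_of_node[v] for v in shared}
            ari, _ = compare_partitions(pa, pb)
            aris.append(ari)
        return min(aris) if aris else 1.0

    if not report.empty:
        report["ari_neighbours"] = [
            _neighbour_ari(t) if t in neighbours else np.nan for t in report["tau"]
        ]
    selected = None
    for t in reversed(grid):
        if nets.get(t) is None:
            continue
        row = report.loc[report["tau"] == t].iloc[0]
        if row["giant_frac"] >= min_component_frac and row["ari_neighbours"] >= stability_min:
            selected = t
            break
    if selected is None:
        raise ThresholdSelectionError(report)
    logger.info("select_threshold: tau=%.4g (grid of %d)", selected, len(grid))
    return selected, report
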