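"""End-to-end orchestration: expression input -> DE screen -> four networks
(per group x {DE, CO} gene universe) -> connectivity, scale-free fit, node
hierarchy, communities and coarse-grained community structure -> JSON report.

The report mirrors a two-group comparison: for each network it records N, L,
the selected threshold tau, connectivity k = 2L/N, the power-law fit, the
number of communities and modularity Q, node-category counts and the top-k
coarse-grained table, plus a cross-network comparison block.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .community import (
    Partition,
    coarse_grain,
    community_letters,
    detect_communities,
    top_communities,
)
from .expression import (
    ExpressionMatrix,
    differential_expression,
    filter_gene_universe,
    read_expression_matrix,
)
from .hierarchy import CATEGORIES, classify_nodes
from .network import (
    build_network,
    connectivity,
    correlation_matrix,
    degree_distribution,
    select_threshold,
)
from .scalefree import powerlaw_fit_ks

logger = logging.getLogger("coexnet")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "compare_networks"]

_DE_GRID = [round(t, 3) for t in np.arange(0.930, 0.9801, 0.005)]
_CO_GRID = [round(t, 3) for t in np.arange(0.990, 0.9981, 0.001)]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; all thresholds and seeds are explicit."""

    expression_path: str | None = None
    group_map_path: str | None = None
    keep_genes_path: str | None = None
    groups: tuple[str, str] | None = None   # (A, B); direction = mean(A) - mean(B)
    de_alpha: float = 0.05
    de_variant: str = "student"
    tau_grid_de: list = field(default_factory=lambda: list(_DE_GRID))
    tau_grid_co: list = field(default_factory=lambda: list(_CO_GRID))
    stability_delta: float | None = None    # None = one grid step
    min_component_frac: float = 0.8
    stability_min: float = 0.8
    hub_quantile: float = 0.9
    vip_k0_quantile: float = 0.5
    seed: int = 0
    n_restarts: int = 10
    scan_restarts: int = 2                  # cheaper Louvain during the tau scan
    powerlaw_bootstrap_reps: int = 0
    top_k_communities: int = 9
    keep_communities: list = field(default_factory=list)
    min_de_genes: int = 3
    out_dir: str | None = None


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, message: str, partial: dict | None = None):
        self.stage = stage
        self.partial = partial or {}
        super().__init__(f"pipeline stage '{stage}' failed: {message}")


def _maybe_write(out_dir, name, writer):
    if out_dir is not None:
        writer(Path(out_dir) / name)


def _analyze_network(net, cfg: PipelineConfig, out_dir, name: str) -> dict:
    n, l = net.number_of_nodes(), net.number_of_edges()
    logger.info("[%s] N=%d L=%d tau=%s", name, n, l, net.graph.get("tau"))
    k = connectivity(net)
    dd = degree_distribution(net)
    degs = [d for _, d in net.degree()]
    try:
        pl = powerlaw_fit_ks(degs, bootstrap_reps=cfg.powerlaw_bootstrap_reps,
                             seed=cfg.seed).to_dict()
    except ValueError as exc:
        pl = {"error": str(exc)}
    hier = classify_nodes(net, cfg.hub_quantile, cfg.vip_k0_quantile)
    part = detect_communities(net, seed=cfg.seed, n_restarts=cfg.n_restarts)
    letters = community_letters(part.n_communities)
    letter_of = {i: letters[i] for i in range(part.n_communities)}
    coarse = coarse_grain(net, part)
    top = top_communities(coarse, min(cfg.top_k_communities, part.n_communities),
                          keep=cfg.keep_communities)

    _maybe_write(out_dir, f"{name}_edges.tsv", lambda p: cio.write_edge_list(net, p))
    _maybe_write(out_dir, f"{name}.graphml", lambda p: cio.write_graphml(net, p))
    _maybe_write(out_dir, f"{name}_degree_distribution.tsv",
                 lambda p: dd.to_csv(p, sep="\t", index=False))
    _maybe_write(out_dir, f"{name}_hierarchy.tsv",
                 lambda p: hier.to_csv(p, sep="\t", index=False))
    _maybe_write(out_dir, f"{name}_partition.tsv",
                 lambda p: cio.write_partition(part, p, letters=letter_of))
    _maybe_write(out_dir, f"{name}_cgcs.json", lambda p: cio.write_json(top.to_dict(), p))

    return {
        "n_nodes": n,
        "n_edges": l,
        "tau": net.graph.get("tau"),
        "k": k,
        "powerlaw": pl,
        "n_communities": part.n_communities,
        "q": part.q,
        "hierarchy_counts": {c: int((hier["category"] == c).sum()) for c in CATEGORIES},
        "cgcs_top": top.to_dict(),
    }


def run_pipeline(config: PipelineConfig, matrix: ExpressionMatrix | None = None) -> dict:
    """Run every stage and return the report bundle (also written as JSON
    when ``config.out_dir`` is set). Any stage failure raises
    :class:`PipelineStageError` naming the stage and carrying the partial
    report of the completed stages."""
    cfg = config
    out_dir = cfg.out_dir
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in dataclasses.asdict(cfg).items()},
                    "stages": [], "networks": {}}

    # --- read + filter -----------------------------------------------------
    try:
        if matrix is None:
            if cfg.expression_path is None or cfg.group_map_path is None:
                raise ValueError("expression_path and group_map_path are required")
            matrix = read_expression_matrix(cfg.expression_path, cfg.group_map_path)
        if cfg.keep_genes_path:
            keep = [ln.strip() for ln in Path(cfg.keep_genes_path).read_text().splitlines()
                    if ln.strip()]
            matrix = filter_gene_universe(matrix, keep)
    except Exception as exc:
        raise PipelineStageError("read_expression", str(exc), report) from exc
    groups = tuple(cfg.groups) if cfg.groups else tuple(matrix.groups)
    report["groups"] = list(groups)
    report["n_genes"] = len(matrix.genes)
    report["stages"].append("read_expression")
    logger.info("read %d genes x %d samples; groups %s", len(matrix.genes),
                len(matrix.samples), groups)

    # --- DE screen ---------------------------------------------------------
    try:
        de = differential_expression(matrix, alpha=cfg.de_alpha,
                                     variant=cfg.de_variant, group_order=groups)
        de_genes = list(de.loc[de["significant"], "gene"])
        report["de"] = {
            "alpha": cfg.de_alpha,
            "variant": cfg.de_variant,
            "n_tested": int(len(de)),
            "n_significant": len(de_genes),
            "n_up": int(((de["direction"] == "up") & de["significant"]).sum()),
            "n_down": int(((de["direction"] == "down") & de["significant"]).sum()),
        }
        _maybe_write(out_dir, "de_table.tsv", lambda p: de.to_csv(p, sep="\t", index=False))
        if len(de_genes) < cfg.min_de_genes:
            raise ValueError(
                f"only {len(de_genes)} significant genes at alpha={cfg.de_alpha}; "
                f"cannot build DE networks (need >= {cfg.min_de_genes})"
            )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("differential_expression", str(exc), report) from exc
    report["stages"].append("differential_expression")
    logger.info("DE screen: %d significant of %d", len(de_genes), len(de))

    # --- per group x universe networks ------------------------------------
    universes = {"DE": de_genes, "CO": matrix.genes}
    for group in groups:
        for uname, genes in universes.items():
            net_name = f"{group}-{uname}"
            try:
                sub = filter_gene_universe(matrix, genes)
                corr = correlation_matrix(sub, group)
                grid = cfg.tau_grid_de if uname == "DE" else cfg.tau_grid_co
                tau, scan = select_threshold(
                    corr, grid,
                    stability_delta=cfg.stability_delta,
                    min_component_frac=cfg.min_component_frac,
                    stability_min=cfg.stability_min,
                    seed=cfg.seed, n_restarts=cfg.scan_restarts,
                )
                net = build_network(corr, tau)
                entry = _analyze_network(net, cfg, out_dir, net_name)
                entry["threshold_scan"] = scan.to_dict(orient="records")
                report["networks"][net_name] = entry
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(f"network[{net_name}]", str(exc), report) from exc
            report["stages"].append(f"network[{net_name}]")

    # --- cross-network comparison ------------------------------------------
    names = list(report["networks"])
    comparisons = {}
    for uname in universes:
        pair = [f"{g}-{uname}" for g in groups]
        if all(p in report["networks"] for p in pair):
            comparisons["_vs_".join(pair)] = compare_networks(
                report["networks"][pair[0]], report["networks"][pair[1]]
            ).to_dict(orient="records")
    report["comparisons"] = comparisons
    report["stages"].append("comparison")
    if out_dir is not None:
        cio.write_json(report, Path(out_dir) / "report.json")
    return report


_COMPARE_FIELDS = [
    ("n_nodes", "N"), ("n_edges", "L"), ("k", "k"), ("q", "Q"),
    ("n_communities", "n_communities"),
]


def compare_networks(a: dict, b: dict) -> pd.DataFrame:
    """Side-by-side metric table for two report entries (difference = a - b)."""
    rows = []
    def _one(metric, va, vb):
        avail = va is not None and vb is not None
        rows.append({
            "metric": metric,
            "a": va, "b": vb,
            "diff": (va - vb) if avail else None,
            "ratio": (va / vb) if avail and vb not in (0, None) else None,
            "available": bool(avail),
        })
    for key, label in _COMPARE_FIELDS:
        _one(label, a.get(key), b.get(key))
    ha = a.get("hierarchy_counts") or {}
    hb = b.get("hierarchy_counts") or {}
    for cat in CATEGORIES:
        _one(f"n_{cat}", ha.get(cat), hb.get(cat))
    return pd.DataFrame(rows)
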