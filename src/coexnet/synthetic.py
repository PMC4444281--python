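"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline is testable without external data:

* :func:`generate_modular_expression` emulates a two-group microarray design
  (log-scale intensities, a handful of samples per group, a planted modular
  correlation structure and a planted set of up/down-regulated genes);
* :func:`generate_planted_partition_graph` gives a stochastic-block-model
  benchmark for community detection;
* :func:`generate_scale_free_graph` (preferential attachment) and
  :func:`generate_er_graph` (Erdős–Rényi) are positive and negative controls
  for the power-law degree-distribution test.

The expression model is a single latent factor per module and group: gene g
in module m observed on sample s is

    x[g, s] = baseline + noise_sd * (sign_g * sqrt(c) * f[m, s]
                                     + sqrt(1 - c) * eps[g, s])  (+ DE shift)

with f and eps standard normal, so the expected within-module Pearson
correlation between same-sign genes is exactly c = ``module_corr`` and the
marginal variance of every gene is ``noise_sd**2``. Half the loadings in each
module are negative, so covariation is both positive and negative and the
absolute-value edge rule is exercised. Differentially expressed genes get a
mean shift of ``effect_size * noise_sd`` (up) or its negative (down) in group
A only.

Module factors are planted at *minimum mutual coherence* rather than drawn
independently: with only a few samples per group, independent factor vectors
collide by chance (two of eight standard-normal vectors in a 7-sample space
routinely show |r| > 0.7, occasionally > 0.9), which silently merges planted
modules and makes the ground truth unrecoverable by any method — the same
reason a planted-partition benchmark refuses p_in <= p_out. Factors are
therefore initialised from seeded Gaussians, centred and standardised, and
their pairwise sample correlations driven down to the packing limit imposed
by the sample size (~|r| = 0.2 for 8 factors on 7 samples) by projected
gradient descent. The procedure is deterministic given the seed.

Randomness is hierarchical: one integer seed spawns independent per-module and
per-gene streams, so enlarging the gene set does not perturb the draws of
earlier genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_modular_expression",
    "generate_planted_partition_graph",
    "generate_scale_free_graph",
    "generate_er_graph",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-group modular expression generator."""

    n_genes: int
    n_modules: int
    module_corr: float
    de_fraction: float = 0.0
    effect_size: float = 0.0
    noise_sd: float = 1.0
    n_samples_per_group: int = 7
    seed: int = 0
    baseline: float = 8.0
    group_labels: tuple[str, str] = ("E", "L")

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be a positive integer, got {self.n_genes}")
        if self.n_samples_per_group < 1:
            raise ValueError(
                f"n_samples_per_group must be a positive integer, got {self.n_samples_per_group}"
            )
        if not (1 <= self.n_modules <= self.n_genes):
            raise ValueError(
                f"n_modules must be in [1, n_genes={self.n_genes}], got {self.n_modules}"
            )
        if not (0.0 <= self.module_corr < 1.0):
            raise ValueError(f"module_corr must be in [0, 1), got {self.module_corr}")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset or benchmark graph."""

    module_of_gene: dict = field(default_factory=dict)
    de_genes_up: set = field(default_factory=set)
    de_genes_down: set = field(default_factory=set)
    community_of_node: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def de_genes(self) -> set:
        return self.de_genes_up | self.de_genes_down

    def to_dict(self) -> dict:
        return {
            "module_of_gene": dict(self.module_of_gene),
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "community_of_node": {str(k): v for k, v in self.community_of_node.items()},
        }


def _module_factors(
    seed: int, group_index: int, n_modules: int, n_samples: int
) -> np.ndarray:
    """(n_modules x n_samples) factor matrix: mean 0, sd 1 per row, pairwise
    sample correlations pushed to the minimum the sample size allows."""
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(0, group_index))
    )
    f = rng.standard_normal((n_modules, n_samples))
    if n_samples < 3 or n_modules == 1:
        if n_samples >= 2:
            f = (f - f.mean(1, keepdims=True)) / f.std(1, keepdims=True)
        return f
    # coherence minimisation on unit-norm centred rows
    u = f - f.mean(1, keepdims=True)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    step = 0.1
    for _ in range(300):
        gram = u @ u.T
        np.fill_diagonal(gram, 0.0)
        grad = gram @ u          # d/du_i of sum_{j != i} r_ij^2 (up to factor 2)
        u = u - step * grad
        u -= u.mean(1, keepdims=True)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * np.sqrt(n_samples)  # per-row sample sd = 1


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_modular_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate one expression matrix per group plus the planted truth.

    Genes are assigned to modules in contiguous blocks of near-equal size; DE
    genes are drawn uniformly without replacement and split half up / half
    down. Identical spec (including seed) gives bit-identical output.
    """
    n, c = spec.n_genes, spec.module_corr
    genes = _gene_ids(n)
    module_of_gene = {g: (i * spec.n_modules) // n for i, g in enumerate(genes)}

    # dedicated streams: factor matrix per group, noise per gene, DE pick
    factors = {
        gi: _module_factors(spec.seed, gi, spec.n_modules, spec.n_samples_per_group)
        for gi in range(2)
    }

    de_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    n_de = spec.n_de
    de_pick = list(de_rng.choice(n, size=n_de, replace=False)) if n_de else []
    n_up = (n_de + 1) // 2
    up_idx = set(de_pick[:n_up])
    down_idx = set(de_pick[n_up:])

    load = np.sqrt(c) * spec.noise_sd
    resid = np.sqrt(1.0 - c) * spec.noise_sd
    # position within the module decides the loading sign (half negative)
    pos_in_module: dict[str, int] = {}
    counts = [0] * spec.n_modules
    for g in genes:
        m = module_of_gene[g]
        pos_in_module[g] = counts[m]
        counts[m] += 1

    mats = []
    for gi in range(2):
        x = np.empty((n, spec.n_samples_per_group))
        for i, g in enumerate(genes):
            m = module_of_gene[g]
            sign = 1.0 if pos_in_module[g] % 2 == 0 else -1.0
            rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(2, gi, i))
            )
            eps = rng.standard_normal(spec.n_samples_per_group)
            row = spec.baseline + sign * load * factors[gi][m] + resid * eps
            if gi == 0:  # DE shift planted in group A only
                if i in up_idx:
                    row = row + spec.effect_size * spec.noise_sd
                elif i in down_idx:
                    row = row - spec.effect_size * spec.noise_sd
            x[i] = row
        mats.append(x)
    truth = GroundTruth(
        module_of_gene=module_of_gene,
        de_genes_up={genes[i] for i in up_idx},
        de_genes_down={genes[i] for i in down_idx},
    )
    out = []
    for gi, label in enumerate(spec.group_labels):
        samples = [f"{label}{j:02d}" for j in range(1, spec.n_samples_per_group + 1)]
        df = pd.DataFrame(mats[gi], index=genes, columns=samples)
        out.append(ExpressionMatrix(df, {s: label for s in samples}))
    return out[0], out[1], truth


def generate_planted_partition_graph(
    n_nodes: int, n_communities: int, p_in: float, p_out: float, seed: int
) -> tuple[nx.Graph, GroundTruth]:
    """Stochastic-block-model benchmark with near-equal block sizes.

    Intra-block pairs are joined independently with probability ``p_in``,
    inter-block pairs with ``p_out``; requires ``p_in > p_out`` so the planted
    structure is recoverable (equality would be an unstructured G(n, p)).
    """
    if n_nodes < 1:
        raise ValueError(f"n_nodes must be positive, got {n_nodes}")
    if not (1 <= n_communities <= n_nodes):
        raise ValueError(f"n_communities must be in [1, n_nodes], got {n_communities}")
    if not (p_in > p_out) and n_communities > 1:
        raise ValueError(f"p_in ({p_in}) must exceed p_out ({p_out})")
    base = n_nodes // n_communities
    sizes = [base + (1 if i < n_nodes % n_communities else 0) for i in range(n_communities)]
    probs = [
        [p_in if i == j else p_out for j in range(n_communities)]
        for i in range(n_communities)
    ]
    g = nx.stochastic_block_model(sizes, probs, seed=seed)
    community = {node: g.nodes[node]["block"] for node in g}
    plain = nx.Graph()
    plain.add_nodes_from(g.nodes())
    plain.add_edges_from(g.edges())
    return plain, GroundTruth(community_of_node=community)


def generate_scale_free_graph(n_nodes: int, m_attach: int, seed: int) -> nx.Graph:
    """Barabási–Albert preferential-attachment graph (connected, L ≈ m(n−m))."""
    if not (1 <= m_attach < n_nodes):
        raise ValueError(
            f"m_attach must satisfy 1 <= m_attach < n_nodes, got {m_attach} vs {n_nodes}"
        )
    return nx.barabasi_albert_graph(n_nodes, m_attach, seed=seed)


def generate_er_graph(n_nodes: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi G(n, p) — the Poisson-degree negative control."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    return nx.gnp_random_graph(n_nodes, p, seed=seed)
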