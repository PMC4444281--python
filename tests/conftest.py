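import networkx as nx
import numpy as np
import pytest

from coexnet import SyntheticSpec, concat_groups, generate_modular_expression


@pytest.fixture(scope="session")
def modular_dataset():
    """A mid-size two-group dataset with strong planted structure."""
    spec = SyntheticSpec(
        n_genes=500, n_modules=4, module_corr=0.8, de_fraction=0.1,
        effect_size=3.0, noise_sd=1.0, n_samples_per_group=7, seed=11,
    )
    em_a, em_b, truth = generate_modular_expression(spec)
    return spec, concat_groups(em_a, em_b), truth


def random_connected_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """G(n, p) conditioned on connectivity (retry with fresh seeds)."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() and nx.is_connected(g):
            return g
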