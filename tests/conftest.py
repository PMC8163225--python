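import numpy as np
import pytest

from metnetpca.data_network import DataMatrix, build_data_network, uv_scale
from metnetpca.metnet import CompoundGraph, carbon_filter, remove_side_compounds
from metnetpca.netpca import fit_netpca
from metnetpca.synthetic import (
    NetworkDesign,
    generate_cohort,
    generate_toy_network,
    paper_design,
)


@pytest.fixture(scope="session")
def cohort():
    """Paper-design synthetic cohort (seed 42): scaled network, truth, fitted model."""
    network, truth = generate_cohort(paper_design(seed=42))
    scaled, _ = uv_scale(network)
    model = fit_netpca(scaled, n_components=2)
    return {"raw": network, "scaled": scaled, "truth": truth, "model": model}


@pytest.fixture(scope="session")
def toy_network():
    """Default toy metabolic network (seed 11) plus its carbon-filtered,
    side-compound-free version."""
    toy = generate_toy_network(NetworkDesign(seed=11))
    filtered = carbon_filter(remove_side_compounds(toy.graph))
    return {"toy": toy, "filtered": filtered}


@pytest.fixture
def chain_graph():
    """A-B-C-D-E path graph with all-carbon edges."""
    g = CompoundGraph()
    for n in "ABCDE":
        g.add_metabolite(n)
    for u, v in zip("ABCD", "BCDE"):
        g.add_reaction_edge(u, v, f"r{u}{v}", carbon_transfer=True)
    return g


def random_data_network(rng, n_row_classes=2, n_col_classes=2, n_obs=5, n_vars=4):
    """Small random but structurally valid data network."""
    matrices = []
    for i in range(n_row_classes):
        obs = [f"g{i}_o{k}" for k in range(n_obs)]
        for j in range(n_col_classes):
            vs = [f"b{j}_v{k}" for k in range(n_vars)]
            matrices.append(
                DataMatrix(rng.normal(size=(n_obs, n_vars)), obs, vs, f"g{i}", f"b{j}")
            )
    return build_data_network(matrices)
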