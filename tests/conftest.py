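import itertools

import numpy as np
import pytest

from cbpln import (
    GeneSetCollection,
    PerturbationTable,
    WeightedNetwork,
    restrict_to_annotated,
)


@pytest.fixture
def toy_genesets():
    """Two overlapping sets sharing gene c1."""
    return GeneSetCollection(
        {"A": frozenset({"a1", "a2", "c1"}), "B": frozenset({"b1", "b2", "c1"})}
    )


@pytest.fixture
def toy_network():
    return WeightedNetwork.from_edges(
        [("a1", "b1", 0.8), ("a2", "b1", 0.5), ("a2", "b2", 1.0), ("a1", "c1", 0.9)]
    )


@pytest.fixture
def toy_scores():
    return PerturbationTable({"a1": 2.0, "a2": 1.0, "b1": 3.0, "b2": 2.0, "c1": 4.0})


def random_problem(seed, n_genes=60, n_sets=4, set_size=10, edge_p=0.08):
    """Small random (network, genesets, scores) triple for property tests."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    sets = {}
    for k in range(n_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        sets[f"S{k}"] = frozenset(members.tolist())
    gs = GeneSetCollection(sets)
    edges = []
    for i, j in itertools.combinations(range(n_genes), 2):
        if rng.random() < edge_p:
            edges.append((genes[i], genes[j], float(rng.uniform(0.2, 1.0))))
    net = WeightedNetwork.from_edges(edges)
    pvals = {g: float(rng.uniform(0.0, 1.0)) for g in genes}
    table = PerturbationTable.from_pvalues(pvals)
    return restrict_to_annotated(net, gs), gs, table


@pytest.fixture
def random_problem_factory():
    return random_problem


def unit_table(genes):
    """All-ones perturbation scores (p = 0.1 at base 10)."""
    return PerturbationTable.from_pvalues({g: 0.1 for g in genes})
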