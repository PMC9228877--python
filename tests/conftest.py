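import dataclasses

import numpy as np
import pytest

from pathcom import GeneSet, GeneSetCollection, PathwayGraph, build_graph, louvain
from pathcom.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_data():
    """The default planted-community collection (K=5, seed 7)."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def default_graph(default_data):
    return build_graph(default_data.collection)


@pytest.fixture(scope="session")
def default_partition(default_graph):
    return louvain(default_graph, resolution=0.4, seed=0)


@pytest.fixture(scope="session")
def disjoint_data():
    """Fully separable variant: every gene of a pathway from its own pool."""
    return generate(dataclasses.replace(SyntheticSpec(), within_fraction=1.0))


@pytest.fixture(scope="session")
def disjoint_graph(disjoint_data):
    return build_graph(disjoint_data.collection)


@pytest.fixture()
def two_triangles():
    """Two disjoint unit-weight triangles: Q of the obvious split is 1/2."""
    edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
    return PathwayGraph(["a", "b", "c", "x", "y", "z"], edges)


def graph_from_matrix(weights: np.ndarray) -> PathwayGraph:
    n = weights.shape[0]
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j], float(weights[i, j]))
        for i in range(n) for j in range(i + 1, n)
        if weights[i, j] > 0
    ]
    return PathwayGraph(nodes, edges)


def toy_collection() -> GeneSetCollection:
    """Six pathways in two obvious blocks over a 60-gene universe."""
    genes = [f"G{i:03d}" for i in range(60)]
    blocks = {
        "KEGG_A1": genes[0:12], "KEGG_A2": genes[2:14], "REACTOME_A3": genes[4:16],
        "KEGG_B1": genes[30:42], "GOBP_B2": genes[32:44], "REACTOME_B3": genes[34:46],
    }
    return GeneSetCollection(
        [GeneSet(pid, pid, pid.split("_")[0], frozenset(g)) for pid, g in blocks.items()]
    )
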