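import numpy as np
import pytest

from phenonet import InteractionNetwork, build_module


@pytest.fixture
def path_graph():
    """The worked micro-example network: a chain a-b-c-d."""
    return InteractionNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def path_modules(path_graph):
    mod = lambda name, genes: build_module(path_graph, name, set(genes))
    return {
        "ab": mod("ab", "ab"),
        "cd": mod("cd", "cd"),
        "bc": mod("bc", "bc"),
        "ad": mod("ad", "ad"),
        "abd": mod("abd", "abd"),
    }


def random_graph_cases(n_graphs: int, seed: int = 0, max_n: int = 50):
    """Random (nodes, edges, module_a, module_b) cases for oracle comparisons.

    Graph sizes and densities vary; modules are random subsets of size >= 2.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_graphs):
        n = int(rng.integers(5, max_n + 1))
        p = float(rng.uniform(0.03, 0.4))
        nodes = [f"v{i}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        size_a = int(rng.integers(2, max(3, n // 2 + 1)))
        size_b = int(rng.integers(2, max(3, n // 2 + 1)))
        mem_a = set(rng.choice(nodes, size=size_a, replace=False))
        mem_b = set(rng.choice(nodes, size=size_b, replace=False))
        cases.append((nodes, edges, mem_a, mem_b))
    return cases
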