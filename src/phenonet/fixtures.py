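"""Deterministic synthetic-data generators.

Everything the pipeline consumes — interactome, phenotype→gene annotations,
a toy GO with gene annotations, and a gene×condition expression matrix — can
be generated here with controllable structure: Erdős–Rényi background
networks, planted dense modules (phenotype protein sets that truly
agglomerate), module pairs with designed overlap, nested ontology annotation
blocks, and Gaussian-copula expression blocks.  All generators are pure
functions of their parameters and seed.

The emphasis is on *structure*, not on mimicking the real interactome's
degree distribution; a Barabási–Albert background is available for
robustness checks.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ExpressionMatrix
from .network import InteractionNetwork
from .ontology import AnnotationTable, OntologyDAG


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _node_name(i: int) -> str:
    return f"P{i:04d}"


def generate_network(
    n_nodes: int, edge_prob: float, seed, model: str = "er"
) -> InteractionNetwork:
    """Random background interactome with string node labels.

    ``model="er"`` gives Erdős–Rényi G(n, p); ``model="ba"`` a Barabási–Albert
    graph whose attachment parameter is chosen to roughly match the ER edge
    count (robustness-check variant).
    """
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = _rng(seed)
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if model == "er":
        g = nx.gnp_random_graph(n_nodes, edge_prob, seed=nx_seed)
    elif model == "ba":
        m = max(1, round(edge_prob * (n_nodes - 1) / 2))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=nx_seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    g = nx.relabel_nodes(g, {i: _node_name(i) for i in g.nodes})
    return InteractionNetwork(g)


def _plant_edges(
    network: InteractionNetwork, nodes: list, p_in: float, rng: np.random.Generator
) -> None:
    """Add internal edges among ``nodes`` independently at rate p_in (in place)."""
    ordered = sorted(nodes)
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            if rng.random() < p_in:
                network.graph.add_edge(ordered[a], ordered[b])


def plant_module(
    network: InteractionNetwork, size: int, p_in: float, seed
) -> frozenset:
    """Pick ``size`` nodes and densify them at rate ``p_in`` (mutates the network).

    Returns the planted node set — a phenotype protein set that agglomerates.
    """
    if size > network.number_of_nodes:
        raise ValueError(f"cannot plant {size} nodes in {network.number_of_nodes}")
    rng = _rng(seed)
    nodes = network.node_list()
    idx = rng.choice(len(nodes), size=size, replace=False)
    chosen = [nodes[i] for i in idx]
    _plant_edges(network, chosen, p_in, rng)
    return frozenset(chosen)


def generate_overlap_series(
    network: InteractionNetwork,
    base_size: int,
    overlaps: list[int],
    seed,
    p_in: float = 0.5,
) -> list[tuple[frozenset, frozenset]]:
    """Planted module pairs sharing exactly k nodes, one pair per k in ``overlaps``.

    One base module A is planted; for each requested overlap k the partner
    shares the first k nodes of a fixed shuffle of A (so partners are nested)
    plus a fresh disjoint block, itself planted at ``p_in``.  Mutates the
    network.
    """
    if any(k > base_size or k < 0 for k in overlaps):
        raise ValueError("each overlap must be between 0 and base_size")
    fresh_needed = sum(base_size - k for k in overlaps)
    if base_size + fresh_needed > network.number_of_nodes:
        raise ValueError("network too small for the requested overlap series")
    rng = _rng(seed)
    nodes = network.node_list()
    perm = rng.permutation(len(nodes))
    pool = [nodes[i] for i in perm]
    base = pool[:base_size]
    cursor = base_size
    _plant_edges(network, base, p_in, rng)
    base_order = [str(v) for v in rng.permutation(base)]
    pairs = []
    for k in overlaps:
        partner = base_order[:k] + pool[cursor: cursor + (base_size - k)]
        cursor += base_size - k
        _plant_edges(network, partner, p_in, rng)
        pairs.append((frozenset(base), frozenset(partner)))
    return pairs


def generate_toy_go(
    n_genes: int, depth: int, branching: int, seed
) -> tuple[OntologyDAG, AnnotationTable]:
    """Balanced is_a tree with leaves annotated by disjoint gene blocks.

    Genes are shuffled, split into near-equal contiguous blocks, one block per
    leaf; up-propagation then yields nested annotation sets, so genes of one
    block share a small, specific term while cross-block genes share only
    ancestors.  The returned table is *not* propagated.
    """
    if n_genes <= 0 or depth <= 0 or branching <= 0:
        raise ValueError("parameters must be positive")
    rng = _rng(seed)
    root = "TOY:root"
    terms = [root]
    edges: list[tuple[str, str]] = []
    level = [root]
    for d in range(1, depth + 1):
        nxt = []
        for parent in level:
            for b in range(branching):
                child = f"{parent}.{b}" if parent != root else f"TOY:{b}"
                terms.append(child)
                edges.append((child, parent))
                nxt.append(child)
        level = nxt
    leaves = level
    genes = [f"g{i:04d}" for i in range(n_genes)]
    shuffled = [genes[i] for i in rng.permutation(n_genes)]
    blocks = np.array_split(np.arange(n_genes), len(leaves))
    annotations = {
        leaf: frozenset(shuffled[i] for i in block)
        for leaf, block in zip(leaves, blocks)
        if len(block)
    }
    return OntologyDAG(terms, edges), AnnotationTable(annotations, propagated=False)


def generate_expression(
    genes: list[str],
    n_conditions: int,
    block_assignments: dict[str, object],
    within_block_rho: float,
    seed,
) -> ExpressionMatrix:
    """Gaussian-copula expression: genes of one block share a latent factor.

    Each block has a latent condition profile; a gene's profile is
    sqrt(rho)·factor + sqrt(1−rho)·noise, giving within-block pairwise
    correlation ≈ rho (Pearson, and nearly so for Spearman) and ≈ 0 across
    blocks.  Genes without a block assignment are pure noise.
    """
    if not -1 < within_block_rho < 1:
        raise ValueError("within_block_rho must be in (-1, 1)")
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    rng = _rng(seed)
    blocks = sorted({str(b) for b in block_assignments.values()})
    factors = {b: rng.standard_normal(n_conditions) for b in blocks}
    w = np.sqrt(abs(within_block_rho))
    values = np.empty((len(genes), n_conditions))
    for i, g in enumerate(genes):
        noise = rng.standard_normal(n_conditions)
        block = block_assignments.get(g)
        if block is None:
            values[i] = noise
        else:
            values[i] = w * factors[str(block)] + np.sqrt(1 - w**2) * noise
    conditions = [f"cond{j:03d}" for j in range(n_conditions)]
    return ExpressionMatrix(genes=list(genes), conditions=conditions, values=values)


# ---------------------------------------------------------------------------
# the full benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class PlantedBenchmark:
    """A self-contained synthetic study: network, phenotype modules with a
    designed overlap structure, a toy GO annotating the module genes, and a
    blocked expression matrix."""

    network: InteractionNetwork
    modules: dict[str, frozenset]  # phenotype term -> gene/protein set
    overlap_design: dict[tuple[str, str], int]
    p_in: float
    go_dag: OntologyDAG
    go_annotations: AnnotationTable  # unpropagated
    expression: ExpressionMatrix
    seed: int


def generate_benchmark(
    seed: int,
    n_nodes: int = 600,
    edge_prob: float = 0.008,
    module_size: int = 20,
    overlaps: tuple[int, ...] = (16, 16, 16, 12, 12, 12, 8, 8, 8, 4, 4, 4, 0, 0, 0),
    p_in: float = 0.5,
    n_conditions: int = 40,
    within_block_rho: float = 0.7,
) -> PlantedBenchmark:
    """Generate the planted-module benchmark used across the test battery.

    Each entry of ``overlaps`` creates one *pair* of planted size-
    ``module_size`` modules sharing exactly that many proteins; pairs use
    disjoint node pools, so any two modules from different pairs are
    disjoint.  Every module's gene block is annotated to its own GO leaf and
    forms one expression block, so overlapping phenotype pairs score higher
    on both independent references by construction.
    """
    rng = _rng(seed)
    network = generate_network(n_nodes, edge_prob, seed=rng)
    budget = sum(2 * module_size - k for k in overlaps)
    if budget > n_nodes:
        raise ValueError("node budget exceeds network size")
    nodes = network.node_list()
    pool = [nodes[i] for i in rng.permutation(len(nodes))]
    cursor = 0

    modules: dict[str, frozenset] = {}
    design: dict[tuple[str, str], int] = {}
    for pair_idx, k in enumerate(overlaps):
        shared = pool[cursor: cursor + k]
        cursor += k
        only_a = pool[cursor: cursor + module_size - k]
        cursor += module_size - k
        only_b = pool[cursor: cursor + module_size - k]
        cursor += module_size - k
        mod_a = frozenset(shared + only_a)
        mod_b = frozenset(shared + only_b)
        id_a = f"PH:{2 * pair_idx:03d}"
        id_b = f"PH:{2 * pair_idx + 1:03d}"
        _plant_edges(network, sorted(mod_a), p_in, rng)
        _plant_edges(network, sorted(mod_b), p_in, rng)
        modules[id_a] = mod_a
        modules[id_b] = mod_b
        design[(id_a, id_b)] = k

    # toy GO: one leaf per module annotating its genes, under a single root
    root = "TOY:root"
    terms = [root]
    edges = []
    annotations = {}
    for term_id, members in modules.items():
        leaf = f"TOY:{term_id}"
        terms.append(leaf)
        edges.append((leaf, root))
        annotations[leaf] = members
    go_dag = OntologyDAG(terms, edges)
    go_table = AnnotationTable(annotations, propagated=False)

    # expression: one block per module; shared genes go with their first module
    all_genes = sorted(set().union(*modules.values()))
    block_of: dict[str, str] = {}
    for term_id in sorted(modules):
        for g in modules[term_id]:
            block_of.setdefault(g, term_id)
    expression = generate_expression(
        all_genes, n_conditions, block_of, within_block_rho, seed=rng
    )
    return PlantedBenchmark(
        network=network,
        modules=modules,
        overlap_design=design,
        p_in=p_in,
        go_dag=go_dag,
        go_annotations=go_table,
        expression=expression,
        seed=seed,
    )
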