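"""Phenotype network modules and their localization statistics.

A phenotype's module is the subnetwork induced by its annotated proteins that
are present in the interactome.  Whether the module "agglomerates" is tested
against a permutation null of equal-size random protein sets using two
statistics: the size of the largest connected component, and the mean
distance from each member to its nearest co-member measured on the full
network (so a module split across components still gets finite distances
through non-member paths).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .network import InteractionNetwork, Node

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhenotypeModule:
    """A phenotype's protein set intersected with the network, plus induced edges."""

    phenotype_id: str
    members: frozenset
    induced_edges: frozenset  # frozenset node pairs with both endpoints in members


@dataclass(frozen=True)
class LocalizationNull:
    """Permutation null: statistics of random modules of one fixed size."""

    size: int
    sizes: np.ndarray  # largest-component size per draw
    distances: np.ndarray  # mean nearest-co-member distance per draw (NaN if undefined)


@dataclass(frozen=True)
class LocalizationStats:
    """Observed module statistics against the permutation null."""

    phenotype_id: str
    n_members: int
    module_size: int  # s_A: largest connected subnetwork
    mean_distance: float  # d_A: mean nearest-co-member distance
    null_mean_size: float  # mu_1
    null_sd_size: float  # sigma_1
    null_mean_dist: float  # mu_2
    null_sd_dist: float  # sigma_2
    z_size: float
    z_dist: float
    p_size: float
    p_dist: float
    n_perm: int
    n_isolated: int  # members with no reachable co-member


def build_module(
    network: InteractionNetwork, phenotype: str, genes: set
) -> PhenotypeModule:
    """Intersect a phenotype's gene set with the network and take induced edges."""
    genes = set(genes)
    members = frozenset(g for g in genes if g in network)
    dropped = len(genes) - len(members)
    if dropped:
        logger.debug(
            "build_module(%s): %d of %d genes not in network", phenotype, dropped, len(genes)
        )
    if not members:
        logger.warning("build_module(%s): empty module", phenotype)
    sub = network.graph.subgraph(members)
    induced = frozenset(frozenset(e) for e in sub.edges)
    return PhenotypeModule(phenotype, members, induced)


# ---------------------------------------------------------------------------
# raw statistics (hand BFS on plain adjacency dicts: these run inside the
# permutation loop, where graph-view overhead dominates)
# ---------------------------------------------------------------------------

def _largest_component_size(adj: dict, members) -> int:
    remaining = set(members)
    best = 0
    while remaining:
        seed = remaining.pop()
        comp = 1
        stack = [seed]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w in remaining:
                    remaining.discard(w)
                    comp += 1
                    stack.append(w)
        if comp > best:
            best = comp
    return best


def _nearest_comember_distance(adj: dict, v, members: set) -> int | None:
    """Full-network BFS from ``v`` until another member is reached."""
    seen = {v}
    frontier = [v]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w in seen:
                    continue
                if w in members:
                    return d
                seen.add(w)
                nxt.append(w)
        frontier = nxt
    return None


def _mean_nearest_distance(adj: dict, members) -> tuple[float, int]:
    """Mean over members of the nearest-co-member distance.

    Members with no reachable co-member are excluded from the average and
    counted; returns (NaN, count) when every member is isolated.
    """
    mset = set(members)
    total = 0
    n = 0
    n_isolated = 0
    for v in mset:
        d = _nearest_comember_distance(adj, v, mset - {v})
        if d is None:
            n_isolated += 1
        else:
            total += d
            n += 1
    if n == 0:
        return float("nan"), n_isolated
    return total / n, n_isolated


def module_size(network: InteractionNetwork, module: PhenotypeModule) -> int:
    """Number of proteins in the largest connected subnetwork of the module."""
    if not module.members:
        raise ValueError("module_size of an empty module is undefined")
    return _largest_component_size(network.adjacency(), module.members)


def mean_shortest_distance(
    network: InteractionNetwork, module: PhenotypeModule
) -> float:
    """Mean over members of the full-network distance to the closest co-member."""
    if len(module.members) < 2:
        raise ValueError("mean_shortest_distance needs at least 2 members")
    d, n_isolated = _mean_nearest_distance(network.adjacency(), module.members)
    if np.isnan(d):
        raise ValueError("all module members are mutually unreachable")
    if n_isolated:
        logger.debug("mean_shortest_distance: %d isolated members excluded", n_isolated)
    return d


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_random_module(
    network: InteractionNetwork, size: int, rng
) -> set:
    """Uniform sample of ``size`` distinct nodes (randomised phenotype labels)."""
    nodes = network.node_list()
    if size > len(nodes):
        raise ValueError(f"cannot sample {size} nodes from {len(nodes)}")
    rng = _as_rng(rng)
    idx = rng.choice(len(nodes), size=size, replace=False)
    return {nodes[i] for i in idx}


def _degree_bins(network: InteractionNetwork, min_bin: int = 20) -> list[list]:
    """Nodes grouped by degree, small bins merged with neighbours."""
    by_degree: dict[int, list] = {}
    for v in network.node_list():
        by_degree.setdefault(network.graph.degree(v), []).append(v)
    bins: list[list] = []
    current: list = []
    for deg in sorted(by_degree):
        current.extend(by_degree[deg])
        if len(current) >= min_bin:
            bins.append(current)
            current = []
    if current:
        if bins:
            bins[-1].extend(current)
        else:
            bins.append(current)
    return bins


def _sample_degree_binned(
    network: InteractionNetwork, members, rng: np.random.Generator
) -> set:
    """Sample a random set matching the module's degree-bin profile."""
    bins = _degree_bins(network)
    bin_of: dict = {}
    for i, b in enumerate(bins):
        for v in b:
            bin_of[v] = i
    needed: dict[int, int] = {}
    for v in members:
        needed[bin_of[v]] = needed.get(bin_of[v], 0) + 1
    out: set = set()
    for i, k in sorted(needed.items()):
        idx = rng.choice(len(bins[i]), size=k, replace=False)
        out.update(bins[i][j] for j in idx)
    return out


def sample_localization_null(
    network: InteractionNetwork,
    size: int,
    n_perm: int,
    rng,
) -> LocalizationNull:
    """Draw ``n_perm`` uniform random modules of ``size`` nodes, recording both statistics.

    The null depends only on the network and the module size, so it can be
    computed once and shared across modules of equal size.
    """
    rng = _as_rng(rng)
    adj = network.adjacency()
    nodes = network.node_list()
    if size > len(nodes):
        raise ValueError(f"cannot sample {size} nodes from {len(nodes)}")
    sizes = np.empty(n_perm, dtype=float)
    dists = np.empty(n_perm, dtype=float)
    for k in range(n_perm):
        idx = rng.choice(len(nodes), size=size, replace=False)
        sample = {nodes[i] for i in idx}
        sizes[k] = _largest_component_size(adj, sample)
        dists[k], _ = _mean_nearest_distance(adj, sample)
    return LocalizationNull(size=size, sizes=sizes, distances=dists)


def _z(observed: float, mean: float, sd: float, what: str) -> float:
    if sd == 0:
        if observed == mean:
            warnings.warn(f"null {what} has zero variance; z set to 0")
            return 0.0
        warnings.warn(f"null {what} has zero variance; z set to +/-inf")
        return float(np.sign(observed - mean)) * float("inf")
    return (observed - mean) / sd


def localization_stats(
    network: InteractionNetwork,
    module: PhenotypeModule,
    n_perm: int = 100_000,
    rng=None,
    null: LocalizationNull | None = None,
    degree_binned: bool = False,
) -> LocalizationStats:
    """Localization z-scores and empirical p-values against a permutation null.

    The null randomises phenotype-protein associations: ``n_perm`` random
    node sets of the module's size.  z_size = (s_A - mu_1)/sigma_1 and
    z_dist = (d_A - mu_2)/sigma_2 with sample (n-1) standard deviations;
    empirical p-values use the (r+1)/(n+1) pseudocount so they are never 0.
    A precomputed ``null`` for the same network and module size may be passed
    to amortise the permutations across modules.
    """
    if len(module.members) < 2:
        raise ValueError("localization needs at least 2 module members")
    adj = network.adjacency()
    s_obs = _largest_component_size(adj, module.members)
    d_obs, n_isolated = _mean_nearest_distance(adj, module.members)
    if np.isnan(d_obs):
        raise ValueError("all module members are mutually unreachable")

    if null is None:
        rng = _as_rng(rng)
        if degree_binned:
            nodes_sizes = np.empty(n_perm, dtype=float)
            nodes_dists = np.empty(n_perm, dtype=float)
            for k in range(n_perm):
                sample = _sample_degree_binned(network, module.members, rng)
                nodes_sizes[k] = _largest_component_size(adj, sample)
                nodes_dists[k], _ = _mean_nearest_distance(adj, sample)
            null = LocalizationNull(len(module.members), nodes_sizes, nodes_dists)
        else:
            null = sample_localization_null(network, len(module.members), n_perm, rng)
    elif null.size != len(module.members):
        raise ValueError(
            f"null was drawn for size {null.size}, module has {len(module.members)}"
        )
    n_perm = len(null.sizes)

    finite = null.distances[~np.isnan(null.distances)]
    n_dropped_null = n_perm - len(finite)
    if n_dropped_null:
        logger.debug(
            "localization_stats(%s): %d null draws with no reachable pairs dropped",
            module.phenotype_id, n_dropped_null,
        )
    mu1 = float(np.mean(null.sizes))
    sd1 = float(np.std(null.sizes, ddof=1))
    mu2 = float(np.mean(finite))
    sd2 = float(np.std(finite, ddof=1))
    z_size = _z(s_obs, mu1, sd1, "module size")
    z_dist = _z(d_obs, mu2, sd2, "shortest distance")
    p_size = (1 + int(np.sum(null.sizes >= s_obs))) / (n_perm + 1)
    p_dist = (1 + int(np.sum(finite <= d_obs))) / (len(finite) + 1)
    return LocalizationStats(
        phenotype_id=module.phenotype_id,
        n_members=len(module.members),
        module_size=s_obs,
        mean_distance=d_obs,
        null_mean_size=mu1,
        null_sd_size=sd1,
        null_mean_dist=mu2,
        null_sd_dist=sd2,
        z_size=z_size,
        z_dist=z_dist,
        p_size=p_size,
        p_dist=p_dist,
        n_perm=n_perm,
        n_isolated=n_isolated,
    )


def is_localized(
    stats: LocalizationStats, z_threshold: float = 1.6
) -> tuple[bool, bool]:
    """(by_size, by_distance) significance flags.

    A module is localized by size when its largest component is larger than
    random (z_size >= threshold, inclusive) and by distance when members sit
    closer than random (z_dist <= -threshold).
    """
    return (stats.z_size >= z_threshold, stats.z_dist <= -z_threshold)
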