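"""The network-based phenotype similarity score and the separation baseline.

Two phenotype modules are compared through inverse shortest-path similarities:
Sim(i,j) = 1/d(i,j) between proteins, averaged within a module
(intra-similarity) and symmetrically across two modules (inter-similarity).
The final score

    Sim(A, B) = Sim_inter(N_A, N_B) - (Sim_intra(N_A) + Sim_intra(N_B)) / 2

is higher for more similar phenotypes.  The module also implements the
network-separation baseline s_ab = h_ab - (h_aa + h_bb)/2 built from raw
mean shortest distances, where *lower* values mean more similar.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .localization import PhenotypeModule
from .network import InteractionNetwork


@dataclass(frozen=True)
class SimilarityResult:
    """Intra-, inter- and final similarity for a phenotype pair."""

    phenotype_a: str
    phenotype_b: str
    sim_intra_a: float
    sim_intra_b: float
    sim_inter: float
    sim: float


class SimilarityEngine:
    """Computes module similarities on one network with shared distance caches.

    Single-source shortest-path lengths (unweighted hop counts) are cached per
    source node, and intra-similarities per member set, so repeated pairwise
    scoring — e.g. building an empirical null over many module pairs — costs
    one BFS per distinct module member.
    """

    def __init__(self, network: InteractionNetwork) -> None:
        self.network = network
        self._dist: dict = {}
        self._intra: dict[frozenset, float] = {}

    def _distances(self, source) -> dict:
        d = self._dist.get(source)
        if d is None:
            if source not in self.network:
                raise ValueError(f"node {source!r} not in network")
            d = nx.single_source_shortest_path_length(self.network.graph, source)
            self._dist[source] = d
        return d

    # -- Sim(i, j) = 1 / d(i, j) ------------------------------------------

    def pair(self, i, j) -> float:
        """Inverse-distance similarity: 1 for identical nodes, 0 if disconnected."""
        if j not in self.network:
            raise ValueError(f"node {j!r} not in network")
        if i == j:
            return 1.0
        d = self._distances(i).get(j)
        return 0.0 if d is None else 1.0 / d

    def intra(self, module: PhenotypeModule) -> float:
        """Mean of Sim(i, j) over distinct member pairs (diagonal excluded)."""
        members = module.members
        if len(members) < 2:
            raise ValueError("intra-similarity needs at least 2 members")
        cached = self._intra.get(members)
        if cached is not None:
            return cached
        ordered = sorted(members)
        total = 0.0
        for a_idx, i in enumerate(ordered):
            di = self._distances(i)
            for j in ordered[a_idx + 1:]:
                d = di.get(j)
                if d is not None:
                    total += 1.0 / d
        # unordered-pair mean == ordered-pair mean since Sim is symmetric
        value = total / (len(members) * (len(members) - 1) / 2)
        self._intra[members] = value
        return value

    def node_to_module(self, i, module: PhenotypeModule) -> float:
        """Mean of Sim(i, j) over members j, with the i == j term contributing 1."""
        if not module.members:
            raise ValueError("node-to-module similarity of an empty module")
        di = self._distances(i)
        total = 0.0
        for j in sorted(module.members):  # fixed order keeps float sums reproducible
            if j == i:
                total += 1.0
            else:
                d = di.get(j)
                if d is not None:
                    total += 1.0 / d
        return total / len(module.members)

    def inter(self, mod_a: PhenotypeModule, mod_b: PhenotypeModule) -> float:
        """Symmetrised mean of directed node-to-module similarities."""
        if not mod_a.members or not mod_b.members:
            raise ValueError("inter-similarity of an empty module")
        a_to_b = sum(self.node_to_module(i, mod_b) for i in sorted(mod_a.members))
        b_to_a = sum(self.node_to_module(i, mod_a) for i in sorted(mod_b.members))
        return 0.5 * (a_to_b / len(mod_a.members) + b_to_a / len(mod_b.members))

    def score(self, mod_a: PhenotypeModule, mod_b: PhenotypeModule) -> SimilarityResult:
        """The final similarity: inter minus the mean of the two intras."""
        if len(mod_a.members) < 2 or len(mod_b.members) < 2:
            raise ValueError("similarity needs modules with >= 2 members")
        intra_a = self.intra(mod_a)
        intra_b = self.intra(mod_b)
        inter = self.inter(mod_a, mod_b)
        return SimilarityResult(
            phenotype_a=mod_a.phenotype_id,
            phenotype_b=mod_b.phenotype_id,
            sim_intra_a=intra_a,
            sim_intra_b=intra_b,
            sim_inter=inter,
            sim=inter - (intra_a + intra_b) / 2.0,
        )

    def separation(self, mod_a: PhenotypeModule, mod_b: PhenotypeModule) -> float:
        """Network separation s_ab = h_ab - (h_aa + h_bb)/2; lower = more similar.

        h_ab averages shortest distances over cross pairs of *distinct* nodes;
        h_aa, h_bb average over distinct within-module pairs.  Skipping
        identical-node cross pairs (rather than counting them as distance 0)
        makes s(A, A) exactly 0 for any module.  Unreachable pairs are
        excluded from each mean.
        """
        if len(mod_a.members) < 2 or len(mod_b.members) < 2:
            raise ValueError("separation needs modules with >= 2 members")

        def within(members) -> tuple[float, int]:
            ordered = sorted(members)
            total, n = 0.0, 0
            for idx, i in enumerate(ordered):
                di = self._distances(i)
                for j in ordered[idx + 1:]:
                    d = di.get(j)
                    if d is not None:
                        total += d
                        n += 1
            return total, n

        total_ab, n_ab = 0.0, 0
        for i in sorted(mod_a.members):
            di = self._distances(i)
            for j in sorted(mod_b.members):
                if i == j:
                    continue
                d = di.get(j)
                if d is not None:
                    total_ab += d
                    n_ab += 1
        total_aa, n_aa = within(mod_a.members)
        total_bb, n_bb = within(mod_b.members)
        if n_ab == 0 or n_aa == 0 or n_bb == 0:
            raise ValueError("separation undefined: no reachable pairs")
        return total_ab / n_ab - (total_aa / n_aa + total_bb / n_bb) / 2.0


# ---------------------------------------------------------------------------
# functional wrappers (one-shot use; heavy callers should hold an engine)
# ---------------------------------------------------------------------------

def node_pair_similarity(network: InteractionNetwork, i, j) -> float:
    if i not in network or j not in network:
        raise ValueError("both nodes must be in the network")
    return SimilarityEngine(network).pair(i, j)


def intra_similarity(network: InteractionNetwork, module: PhenotypeModule) -> float:
    return SimilarityEngine(network).intra(module)


def node_to_module_similarity(
    network: InteractionNetwork, i, module: PhenotypeModule
) -> float:
    return SimilarityEngine(network).node_to_module(i, module)


def inter_similarity(
    network: InteractionNetwork, mod_a: PhenotypeModule, mod_b: PhenotypeModule
) -> float:
    return SimilarityEngine(network).inter(mod_a, mod_b)


def phenonet_similarity(
    network: InteractionNetwork, mod_a: PhenotypeModule, mod_b: PhenotypeModule
) -> SimilarityResult:
    return SimilarityEngine(network).score(mod_a, mod_b)


def menche_separation(
    network: InteractionNetwork, mod_a: PhenotypeModule, mod_b: PhenotypeModule
) -> float:
    return SimilarityEngine(network).separation(mod_a, mod_b)
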