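"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the score definitions using a plain
hand-rolled all-pairs BFS over dict adjacency — deliberately sharing no code
path with the package (which routes shortest paths through networkx /
early-stopping searches).
"""
from __future__ import annotations

from collections import deque

INF = float("inf")


def adjacency(nodes, edges) -> dict:
    adj = {v: set() for v in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def all_pairs(adj: dict) -> dict:
    """Dense distance table: dist[u][v], absent when unreachable."""
    return {v: bfs_distances(adj, v) for v in adj}


# --- module statistics ------------------------------------------------------

def module_size(dist: dict, members) -> int:
    """Largest connected component of the induced subgraph, from distances.

    Two members are induced-adjacent iff their full-graph distance is 1;
    components are grown by transitive closure over that relation.
    """
    members = list(members)
    comp_of = {}
    best = 0
    for v in members:
        if v in comp_of:
            continue
        comp = {v}
        changed = True
        while changed:
            changed = False
            for w in members:
                if w in comp:
                    continue
                if any(dist[w].get(u) == 1 for u in comp):
                    comp.add(w)
                    changed = True
        for w in comp:
            comp_of[w] = v
        best = max(best, len(comp))
    return best


def mean_shortest_distance(dist: dict, members):
    """Mean nearest-co-member full-graph distance; isolated members excluded.

    Returns (mean, n_isolated); mean is None when no member reaches another.
    """
    vals = []
    n_isolated = 0
    for v in members:
        ds = [dist[v][w] for w in members if w != v and w in dist[v]]
        if ds:
            vals.append(min(ds))
        else:
            n_isolated += 1
    if not vals:
        return None, n_isolated
    return sum(vals) / len(vals), n_isolated


# --- similarity scores ------------------------------------------------------

def sim_ij(dist: dict, i, j) -> float:
    if i == j:
        return 1.0
    d = dist[i].get(j)
    return 0.0 if d is None else 1.0 / d


def intra(dist: dict, members) -> float:
    members = list(members)
    n = len(members)
    total = sum(
        sim_ij(dist, i, j) for i in members for j in members if i != j
    )
    return total / (n * (n - 1))


def node_to_module(dist: dict, i, members) -> float:
    return sum(sim_ij(dist, i, j) for j in members) / len(members)


def inter(dist: dict, mem_a, mem_b) -> float:
    a = sum(node_to_module(dist, i, mem_b) for i in mem_a) / len(mem_a)
    b = sum(node_to_module(dist, i, mem_a) for i in mem_b) / len(mem_b)
    return 0.5 * (a + b)


def phenonet_score(dist: dict, mem_a, mem_b) -> float:
    return inter(dist, mem_a, mem_b) - (intra(dist, mem_a) + intra(dist, mem_b)) / 2.0


def separation(dist: dict, mem_a, mem_b):
    cross = []
    for i in mem_a:
        for j in mem_b:
            if i == j:
                continue  # identical-node pairs are skipped so s(A, A) == 0
            if j in dist[i]:
                cross.append(dist[i][j])

    def within(members):
        members = list(members)
        out = []
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                d = dist[members[x]].get(members[y])
                if d is not None:
                    out.append(d)
        return out

    aa, bb = within(mem_a), within(mem_b)
    if not cross or not aa or not bb:
        return None
    return (
        sum(cross) / len(cross)
        - (sum(aa) / len(aa) + sum(bb) / len(bb)) / 2.0
    )
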