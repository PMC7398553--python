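"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: isomorphism checks go
through networkx's VF2 matcher, connectivity is a direct bitmask flood
fill, automorphisms are found by trying all n! permutations, and expected
values are computed by exhaustive enumeration.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx


def _connected(n: int, adj: list[int]) -> bool:
    seen, frontier = 1, 1
    while frontier:
        nxt = 0
        m = frontier
        while m:
            i = (m & -m).bit_length() - 1
            m &= m - 1
            nxt |= adj[i]
        frontier = nxt & ~seen
        seen |= nxt
    return seen == (1 << n) - 1


def count_connected_isomorphism_classes(n: int) -> int:
    """Count nonisomorphic connected graphs on n nodes by labeled brute
    force: all 2^C(n,2) labeled graphs, connectivity filter, dedup via
    invariant bucketing + pairwise VF2 isomorphism."""
    pairs = list(itertools.combinations(range(n), 2))
    buckets: dict[tuple, list[nx.Graph]] = {}
    for mask in range(1 << len(pairs)):
        adj = [0] * n
        edges = []
        m = mask
        while m:
            k = (m & -m).bit_length() - 1
            m &= m - 1
            u, v = pairs[k]
            adj[u] |= 1 << v
            adj[v] |= 1 << u
            edges.append((u, v))
        if not _connected(n, adj):
            continue
        deg = [a.bit_count() for a in adj]
        nbr_degs = tuple(
            sorted(tuple(sorted(deg[j] for j in range(n) if adj[i] >> j & 1)) for i in range(n))
        )
        tri = sum(
            1
            for a, b, c in itertools.combinations(range(n), 3)
            if adj[a] >> b & 1 and adj[a] >> c & 1 and adj[b] >> c & 1
        )
        cert = (tuple(sorted(deg)), tri, nbr_degs)
        g = nx.Graph(edges)
        g.add_nodes_from(range(n))
        reps = buckets.setdefault(cert, [])
        if not any(nx.is_isomorphic(g, r) for r in reps):
            reps.append(g)
    return sum(len(v) for v in buckets.values())


def brute_force_orbits(n: int, edges) -> tuple[tuple[int, ...], ...]:
    """Node orbits via all n! permutations (adjacency-preserving ones)."""
    eset = {frozenset(e) for e in edges}
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in itertools.permutations(range(n)):
        if all(frozenset((perm[u], perm[v])) in eset for u, v in edges):
            for a in range(n):
                ra, rb = find(a), find(perm[a])
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return tuple(tuple(sorted(g)) for g in sorted(groups.values()))


def pairwise_class_count(graphs: list[nx.Graph]) -> int:
    """Number of isomorphism classes among the given graphs (pairwise VF2)."""
    reps: list[nx.Graph] = []
    for g in graphs:
        if not any(
            nx.faster_could_be_isomorphic(g, r) and nx.is_isomorphic(g, r) for r in reps
        ):
            reps.append(g)
    return len(reps)


def atlas_connected_count(n: int) -> int:
    """Connected-graph count from the published graph atlas (n <= 7)."""
    return sum(
        1
        for g in nx.graph_atlas_g()[1:]
        if g.number_of_nodes() == n and nx.is_connected(g)
    )


def edge_histogram(n: int) -> Counter:
    """Edge-count histogram of connected classes on n nodes, via the atlas."""
    c: Counter = Counter()
    for g in nx.graph_atlas_g()[1:]:
        if g.number_of_nodes() == n and nx.is_connected(g):
            c[g.number_of_edges()] += 1
    return c
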