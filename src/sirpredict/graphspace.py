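"""Exhaustive ensembles of small connected graphs.

The graph model studied here is not a random-graph model: it is the set of
*all* nonisomorphic, connected, simple undirected graphs of a fixed number of
nodes N, every isomorphism class represented exactly once and weighted
equally.  This module enumerates that ensemble for desk-scale N (practical up
to N = 8 in-process; larger precomputed sets can be read from graph6 files),
computes canonical labels used to deduplicate isomorphism classes, and
computes node automorphism orbits, which downstream code uses to avoid
solving the epidemic model repeatedly for structurally equivalent seeds.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "Graph",
    "OrbitPartition",
    "enumerate_connected_graphs",
    "canonical_form",
    "canonical_relabel",
    "node_orbits",
    "edge_count_distribution",
    "read_graph6",
    "write_graph6",
    "MAX_ENUMERATION_NODES",
]

#: Largest N for which in-process enumeration is supported.  The ensemble at
#: N = 9 has 261 080 connected classes and N = 10 has 11.7 million; those are
#: produced offline (e.g. with nauty's ``geng``) and read back as graph6.
MAX_ENUMERATION_NODES = 8


@dataclass(frozen=True)
class Graph:
    """A simple undirected connected graph on nodes 0..N-1.

    ``edges`` stores each edge once with the smaller endpoint first.
    ``graph_id`` is the canonical graph6 label of the graph's isomorphism
    class: two Graphs have equal ``graph_id`` iff they are isomorphic.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    graph_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        n = self.n_nodes
        if n < 1:
            raise ValueError("graph must have at least one node")
        for u, v in self.edges:
            if not (0 <= u < v < n):
                raise ValueError(
                    f"edge ({u}, {v}) invalid for {n} nodes: need 0 <= u < v < n"
                )
        if not _is_connected(n, self.edges):
            raise ValueError("graph is not connected")
        if not self.graph_id:
            object.__setattr__(self, "graph_id", canonical_form(self))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[tuple[int, int]]) -> "Graph":
        norm = frozenset((min(u, v), max(u, v)) for u, v in edges)
        return cls(n_nodes=n_nodes, edges=norm)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        nodes = sorted(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        return cls.from_edges(len(nodes), ((index[u], index[v]) for u, v in g.edges()))

    # -- views ---------------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_masks(self) -> list[int]:
        """Neighbourhoods as bitmasks; bit j of entry i set iff i~j."""
        masks = [0] * self.n_nodes
        for u, v in self.edges:
            masks[u] |= 1 << v
            masks[v] |= 1 << u
        return masks

    def degrees(self) -> list[int]:
        deg = [0] * self.n_nodes
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg


@dataclass(frozen=True)
class OrbitPartition:
    """Partition of a graph's nodes into automorphism orbits."""

    graph_id: str
    orbits: tuple[tuple[int, ...], ...]

    def representative_of(self, node: int) -> int:
        for orbit in self.orbits:
            if node in orbit:
                return orbit[0]
        raise KeyError(node)

    @property
    def representatives(self) -> tuple[int, ...]:
        return tuple(orbit[0] for orbit in self.orbits)


# ---------------------------------------------------------------------------
# connectivity and refinement helpers


def _is_connected(n: int, edges: Iterable[tuple[int, int]]) -> bool:
    if n == 1:
        return True
    masks = [0] * n
    for u, v in edges:
        masks[u] |= 1 << v
        masks[v] |= 1 << u
    seen = 1
    frontier = 1
    while frontier:
        nxt = 0
        m = frontier
        while m:
            i = (m & -m).bit_length() - 1
            m &= m - 1
            nxt |= masks[i]
        frontier = nxt & ~seen
        seen |= nxt
    return seen == (1 << n) - 1


def _refine_colors(n: int, masks: Sequence[int]) -> list[int]:
    """Iterated neighbourhood refinement (1-dimensional colour refinement).

    Returns per-node colour indices; the colouring is an automorphism
    invariant, so any isomorphism maps equal-coloured nodes to each other.
    Colours are assigned in a canonical order (sorted by invariant key), so
    they are comparable between isomorphic graphs.
    """
    colors = [0] * n
    while True:
        keys = []
        for i in range(n):
            nbr = sorted(colors[j] for j in _bits(masks[i]))
            keys.append((colors[i], tuple(nbr)))
        order = sorted(set(keys))
        new = [order.index(k) for k in keys]
        if new == colors:
            return colors
        colors = new


def _bits(mask: int):
    while mask:
        yield (mask & -mask).bit_length() - 1
        mask &= mask - 1


def _cell_permutations(colors: Sequence[int]) -> Iterable[list[int]]:
    """All node orderings that list colour classes in increasing colour order,
    permuting freely within each class.  Every isomorphism between two graphs
    with equal refined colourings is of this form."""
    cells: dict[int, list[int]] = {}
    for i, c in enumerate(colors):
        cells.setdefault(c, []).append(i)
    groups = [cells[c] for c in sorted(cells)]
    for parts in itertools.product(*(itertools.permutations(g) for g in groups)):
        yield [i for part in parts for i in part]


def _edge_code(order: Sequence[int], edges: Iterable[tuple[int, int]], n: int) -> int:
    """Upper-triangular adjacency bitstring of the graph relabelled so that
    ``order[k]`` becomes node k.  Smaller codes sort sparser-first rows."""
    pos = [0] * n
    for k, v in enumerate(order):
        pos[v] = k
    code = 0
    for u, v in edges:
        a, b = pos[u], pos[v]
        if a > b:
            a, b = b, a
        code |= 1 << (a * n + b)
    return code


def _canonical_order(g: Graph) -> list[int]:
    masks = g.adjacency_masks()
    colors = _refine_colors(g.n_nodes, masks)
    best_code = None
    best_order = None
    for order in _cell_permutations(colors):
        code = _edge_code(order, g.edges, g.n_nodes)
        if best_code is None or code < best_code:
            best_code = code
            best_order = order
    assert best_order is not None
    return best_order


def canonical_form(g: Graph) -> str:
    """Canonical label: graph6 encoding of the canonically relabelled graph.

    Two graphs receive the same label iff they are isomorphic.  The label is
    found by colour refinement followed by exhaustive search over the orderings
    the refined colouring permits, minimising the adjacency bitstring; the
    refinement keeps the search tractable for all but the most symmetric
    graphs, and symmetric graphs are few at desk scale.
    """
    order = _canonical_order(g)
    pos = {v: k for k, v in enumerate(order)}
    h = nx.Graph()
    h.add_nodes_from(range(g.n_nodes))
    h.add_edges_from((pos[u], pos[v]) for u, v in g.edges)
    return nx.to_graph6_bytes(h, header=False).decode("ascii").strip()


def canonical_relabel(g: Graph) -> Graph:
    """The canonical representative of g's isomorphism class."""
    order = _canonical_order(g)
    pos = {v: k for k, v in enumerate(order)}
    return Graph.from_edges(g.n_nodes, ((pos[u], pos[v]) for u, v in g.edges))


def node_orbits(g: Graph) -> OrbitPartition:
    """Automorphism orbits of g's nodes.

    Automorphisms must preserve the refined colouring, so it suffices to test
    the orderings compatible with it; orbit classes are the transitive closure
    of all adjacency-preserving ones.
    """
    n = g.n_nodes
    masks = g.adjacency_masks()
    colors = _refine_colors(n, masks)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    base = sorted(range(n), key=lambda i: (colors[i], i))
    base_code = _edge_code(base, g.edges, n)
    for order in _cell_permutations(colors):
        if _edge_code(order, g.edges, n) == base_code:
            # order maps node order[k] -> position k; composed with base this
            # is the automorphism base[k] -> order[k].
            for a, b in zip(base, order):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    cells: dict[int, list[int]] = {}
    for i in range(n):
        cells.setdefault(find(i), []).append(i)
    orbits = tuple(tuple(sorted(c)) for c in sorted(cells.values()))
    return OrbitPartition(graph_id=g.graph_id, orbits=orbits)


# ---------------------------------------------------------------------------
# enumeration


@lru_cache(maxsize=None)
def _all_graphs(n: int) -> tuple[tuple[frozenset[tuple[int, int]], str], ...]:
    """All nonisomorphic simple graphs (connected or not) on n nodes, as
    (edge set, canonical label) pairs.  Built by extending every (n-1)-node
    graph with a new node joined to each subset of the old nodes, then
    deduplicating by canonical label — every n-node graph arises this way
    from deleting one node."""
    if n == 1:
        return ((frozenset(), "single-node"),)
    out: dict[str, frozenset[tuple[int, int]]] = {}
    new = n - 1
    for edges, _ in _all_graphs(n - 1):
        for subset in range(1 << (n - 1)):
            ext = set(edges)
            for j in _bits(subset):
                ext.add((j, new))
            label = _label_any(n, frozenset(ext))
            if label not in out:
                out[label] = frozenset(ext)
    return tuple((out[k], k) for k in sorted(out))


def _label_any(n: int, edges: frozenset[tuple[int, int]]) -> str:
    """Canonical label for a possibly-disconnected graph (enumeration only)."""
    masks = [0] * n
    for u, v in edges:
        masks[u] |= 1 << v
        masks[v] |= 1 << u
    colors = _refine_colors(n, masks)
    best = None
    for order in _cell_permutations(colors):
        code = _edge_code(order, edges, n)
        if best is None or code < best:
            best = code
    return f"{n}:{best:x}"


def enumerate_connected_graphs(n: int) -> list[Graph]:
    """All nonisomorphic connected simple undirected graphs on n nodes.

    Exactly one representative per isomorphism class, each in canonical
    labelling, sorted by canonical label so the ensemble order is
    deterministic and reproducible across runs.

    For n = 6 this returns 112 graphs; the count grows steeply (853 at n = 7,
    11 117 at n = 8), which is why in-process enumeration stops at n = 8.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes for a connected ensemble")
    if n > MAX_ENUMERATION_NODES:
        raise ValueError(
            f"in-process enumeration supports n <= {MAX_ENUMERATION_NODES}; "
            "read larger precomputed sets from graph6 files instead"
        )
    graphs = []
    for edges, _ in _all_graphs(n):
        if _is_connected(n, edges):
            graphs.append(canonical_relabel(Graph(n_nodes=n, edges=edges)))
    graphs.sort(key=lambda g: g.graph_id)
    return graphs


def edge_count_distribution(graphs: Iterable[Graph]) -> dict[int, int]:
    """Histogram of edge counts M across an equal-N collection of graphs.

    The support is always within N-1 <= M <= N(N-1)/2: fewer edges cannot be
    connected, more cannot be simple.
    """
    graphs = list(graphs)
    if not graphs:
        return {}
    sizes = {g.n_nodes for g in graphs}
    if len(sizes) > 1:
        raise ValueError(f"graphs have mixed node counts: {sorted(sizes)}")
    counts = Counter(g.n_edges for g in graphs)
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# graph6 interchange


def read_graph6(path: str | Path) -> list[Graph]:
    """Read one graph per line from a graph6 file (e.g. geng output)."""
    graphs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">>graph6<<"):
            line = line[len(">>graph6<<"):]
        g = nx.from_graph6_bytes(line.encode("ascii"))
        graphs.append(Graph.from_networkx(g))
    return graphs


def write_graph6(graphs: Iterable[Graph], path: str | Path) -> None:
    """Write one graph per line in standard graph6 encoding."""
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(nx.to_graph6_bytes(g.to_networkx(), header=False).decode("ascii"))
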