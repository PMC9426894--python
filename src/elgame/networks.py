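"""Social-structure graph families and their summary statistics.

All families target a mean degree of about 4 so convergence dynamics are
comparable across topologies:

- ``lattice2d`` — square toroidal grid with von Neumann (4-neighbor)
  connectivity; requires ``side**2 == N``.
- ``ring`` — circulant graph, each node tied to its 2 nearest neighbors on
  either side (degree 4).
- ``smallworld`` — Watts-Strogatz rewiring of that ring with probability
  ``ws_p``.
- ``random`` — Erdos-Renyi G(N, p) with p = degree/(N-1).
- ``scalefree`` — Barabasi-Albert preferential attachment, 2 edges per new
  node.
- ``complete`` — fully connected.
- ``regular`` — uniform random 4-regular graph.

Nodes are always labelled ``0..N-1``; lattice nodes additionally carry
``(row, col)`` coordinates (``row = i // side``, ``col = i % side``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "NetworkSpec",
    "build_network",
    "avg_shortest_path",
    "avg_clustering",
    "lattice_coords",
    "write_edgelist",
    "read_edgelist",
    "graph_to_adjacency",
    "adjacency_to_graph",
]

logger = logging.getLogger(__name__)

FAMILIES = ("lattice2d", "ring", "smallworld", "random", "scalefree",
            "complete", "regular")


@dataclass
class NetworkSpec:
    """Parameters of one graph family realization."""

    family: str
    N: int
    side: int | None = None        # lattice2d only
    ws_p: float | None = None      # smallworld only
    degree: int = 4                # target mean degree

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.N < 1:
            raise ValueError("N must be positive")
        if self.family == "lattice2d":
            side = self.side if self.side is not None else int(round(self.N ** 0.5))
            if side * side != self.N:
                raise ValueError(f"lattice2d needs side**2 == N, got N={self.N}")
            self.side = side
        if self.family == "smallworld":
            if self.ws_p is None or not 0.0 <= self.ws_p <= 1.0:
                raise ValueError("smallworld requires ws_p in [0, 1]")


def build_network(spec: NetworkSpec, rng: np.random.Generator) -> nx.Graph:
    """Realize ``spec`` as an undirected simple graph on nodes 0..N-1."""
    N, d = spec.N, spec.degree
    fam = spec.family
    if fam == "lattice2d":
        side = spec.side
        G = nx.grid_2d_graph(side, side, periodic=True)
        G = nx.relabel_nodes(G, {(r, c): r * side + c for r, c in G.nodes})
    elif fam == "ring":
        G = nx.circulant_graph(N, list(range(1, d // 2 + 1)))
    elif fam == "smallworld":
        G = nx.watts_strogatz_graph(N, d, spec.ws_p, seed=rng)
    elif fam == "random":
        G = nx.gnp_random_graph(N, d / (N - 1), seed=rng)
    elif fam == "scalefree":
        G = nx.barabasi_albert_graph(N, d // 2, seed=rng)
    elif fam == "complete":
        G = nx.complete_graph(N)
    elif fam == "regular":
        G = nx.random_regular_graph(d, N, seed=rng)
    else:  # pragma: no cover - guarded by NetworkSpec
        raise ValueError(fam)
    if not nx.is_connected(G):
        logger.warning("%s realization (N=%d) is disconnected: %d components",
                       fam, N, nx.number_connected_components(G))
    return G


def lattice_coords(node: int, side: int) -> tuple[int, int]:
    """(row, col) coordinate of a lattice node."""
    return divmod(node, side)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def avg_shortest_path(G: nx.Graph) -> float:
    """Mean BFS distance over unordered node pairs.

    Disconnected graphs are reduced to their largest component (logged)."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(G):
        logger.warning("avg_shortest_path on disconnected graph: "
                       "using largest component")
        G = G.subgraph(max(nx.connected_components(G), key=len))
    return float(nx.average_shortest_path_length(G))


def avg_clustering(G: nx.Graph) -> float:
    """Mean over nodes of the triangle density of their neighborhood
    (0 for nodes of degree < 2)."""
    if G.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(G))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_edgelist(G: nx.Graph, path) -> None:
    """Whitespace-separated edge list; isolated nodes listed on '#' lines."""
    with open(path, "w") as fh:
        fh.write(f"# N {G.number_of_nodes()}\n")
        for u, v in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{u} {v}\n")


def read_edgelist(path) -> nx.Graph:
    lines = Path(path).read_text().splitlines()
    G = nx.Graph()
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.split()
            if len(parts) == 3 and parts[1] == "N":
                G.add_nodes_from(range(int(parts[2])))
            continue
        u, v = line.split()
        G.add_edge(int(u), int(v))
    return G


def graph_to_adjacency(G: nx.Graph) -> np.ndarray:
    """Boolean adjacency matrix with the 0..N-1 node order."""
    N = G.number_of_nodes()
    adj = np.zeros((N, N), dtype=np.bool_)
    for u, v in G.edges:
        adj[u, v] = adj[v, u] = True
    return adj


def adjacency_to_graph(adj: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(adj.shape[0]))
    iu, ju = np.nonzero(np.triu(adj, 1))
    G.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return G
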