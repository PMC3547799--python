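"""Synthetic population structures: Barabási–Albert scale-free networks.

Every simulation in this package runs on an immutable, connected, simple
undirected graph.  The canonical generator is :func:`generate_ba_network`,
which grows a scale-free network by preferential attachment; user-supplied
topologies can be loaded from plain-text edge lists via
:func:`read_edge_list`.

The in-memory representation keeps both an edge array and a CSR adjacency
(``indptr`` / ``indices``) so that the simulation kernels can iterate over
neighborhoods without per-step allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["Network", "generate_ba_network", "read_edge_list", "write_edge_list"]


@dataclass(frozen=True)
class Network:
    """Immutable undirected simple graph standing for the population structure.

    Parameters
    ----------
    n_nodes : int
        Number of nodes; node ids are the contiguous integers ``0..n_nodes-1``.
    edges : np.ndarray
        ``(n_edges, 2)`` integer array of unordered node pairs, stored with
        ``u < v`` and sorted lexicographically.

    Invariants (enforced at construction): no self-loops, no duplicate edges,
    the graph is connected, and the degree sum equals twice the edge count.
    Connectivity matters dynamically: every node must have at least one
    neighbor to imitate.
    """

    n_nodes: int
    edges: np.ndarray
    indptr: np.ndarray = field(init=False, repr=False, compare=False)
    indices: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValueError("edges must be an (n_edges, 2) array")
        n = int(self.n_nodes)
        if n <= 0:
            raise ValueError("n_nodes must be positive")
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValueError("edge endpoints out of range")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        lo = np.minimum(edges[:, 0], edges[:, 1])
        hi = np.maximum(edges[:, 0], edges[:, 1])
        canon = np.stack([lo, hi], axis=1)
        order = np.lexsort((canon[:, 1], canon[:, 0]))
        canon = canon[order]
        if len(canon) > 1 and np.any(np.all(canon[1:] == canon[:-1], axis=1)):
            raise ValueError("duplicate edges are not allowed")
        object.__setattr__(self, "edges", canon)
        # CSR adjacency over both edge directions
        src = np.concatenate([canon[:, 0], canon[:, 1]])
        dst = np.concatenate([canon[:, 1], canon[:, 0]])
        adj = csr_matrix((np.ones(src.size, dtype=np.int8), (src, dst)), shape=(n, n))
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ValueError(f"graph must be connected (found {n_comp} components)")
        object.__setattr__(self, "indptr", adj.indptr.astype(np.int64))
        object.__setattr__(self, "indices", adj.indices.astype(np.int64))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degree(self) -> np.ndarray:
        """Per-node degree (always >= 1 on a connected graph with n >= 2)."""
        return np.diff(self.indptr)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def neighbors(self, node: int) -> np.ndarray:
        return self.indices[self.indptr[node] : self.indptr[node + 1]]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}


def generate_ba_network(n_nodes: int, m_links: int, seed: int) -> Network:
    """Grow a Barabási–Albert scale-free network.

    Starts from a complete graph on ``m_links + 1`` nodes (so the graph is
    connected and preferential attachment is well defined from the first
    growth step); each subsequent node attaches ``m_links`` edges to distinct
    existing nodes chosen with probability proportional to their current
    degree (sampling without replacement, so the graph stays simple).

    With ``m_links = 2`` the mean degree approaches 4 as ``n_nodes`` grows,
    and the degree distribution develops the characteristic power-law tail
    with exponent near -3.

    Parameters
    ----------
    n_nodes : int
        Final number of nodes; must exceed ``m_links``.
    m_links : int
        Edges added per new node, >= 1.
    seed : int
        Seed for the attachment draws; the same ``(n_nodes, m_links, seed)``
        triple always yields the identical edge set.
    """
    n_nodes = int(n_nodes)
    m_links = int(m_links)
    if m_links < 1:
        raise ValueError("m_links must be >= 1")
    if n_nodes <= m_links:
        raise ValueError("n_nodes must exceed m_links")
    rng = np.random.default_rng(seed)

    m0 = m_links + 1
    edges: list[tuple[int, int]] = [(i, j) for i in range(m0) for j in range(i + 1, m0)]
    # repeated-nodes list: each node appears once per unit of degree, so a
    # uniform draw from it is a degree-proportional draw
    targets = np.empty(2 * (len(edges) + (n_nodes - m0) * m_links), dtype=np.int64)
    pos = 0
    for u, v in edges:
        targets[pos] = u
        targets[pos + 1] = v
        pos += 2

    for new in range(m0, n_nodes):
        chosen: list[int] = []
        seen: set[int] = set()
        while len(chosen) < m_links:
            cand = int(targets[rng.integers(pos)])
            if cand not in seen:
                seen.add(cand)
                chosen.append(cand)
        for tgt in chosen:
            edges.append((tgt, new))
            targets[pos] = tgt
            targets[pos + 1] = new
            pos += 2

    return Network(n_nodes=n_nodes, edges=np.array(edges, dtype=np.int64))


def write_edge_list(network: Network, path) -> None:
    """Serialize as whitespace-separated two-column 0-based edge list."""
    with open(path, "w") as fh:
        for u, v in network.edges:
            fh.write(f"{u} {v}\n")


def read_edge_list(path) -> Network:
    """Read a two-column integer edge list and validate it as a Network.

    Rejects malformed lines (with the offending line number), self-loops,
    duplicate edges and disconnected graphs.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected two columns, got {len(parts)}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer node id") from exc
            if u < 0 or v < 0:
                raise ValueError(f"line {lineno}: negative node id")
            if u == v:
                raise ValueError(f"line {lineno}: self-loop {u}-{v}")
            edges.append((u, v))
    if not edges:
        raise ValueError("empty edge list")
    arr = np.array(edges, dtype=np.int64)
    lo = np.minimum(arr[:, 0], arr[:, 1])
    hi = np.maximum(arr[:, 0], arr[:, 1])
    canon = set(zip(lo.tolist(), hi.tolist()))
    if len(canon) != len(edges):
        raise ValueError("duplicate edges in edge list")
    return Network(n_nodes=int(arr.max()) + 1, edges=arr)
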