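"""Epsilon nearest-neighbor graph over a decoy ensemble.

The nn-graph is the substrate shared by the community- and basin-based
selection methods: vertices are decoys, and an undirected edge joins u and v
whenever their least RMSD d(u, v) is at most a user-chosen epsilon. A small
epsilon can leave the graph disconnected; epsilon is then grown additively a
bounded number of times. Graph density is controlled by capping the number of
nearest neighbors a vertex may keep.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .structures_io import DistanceStore

__all__ = ["NNGraph", "build_nn_graph"]


@dataclass
class NNGraph:
    """Undirected distance-weighted graph over decoy ids.

    ``edges`` is an (m, 2) int array of vertex-index pairs (u < v) with
    parallel ``edge_dist`` weights; adjacency lists are precomputed for the
    descent and minima scans.
    """

    ids: list[str]
    edges: np.ndarray
    edge_dist: np.ndarray
    epsilon_used: float
    connected: bool
    _adj: list[np.ndarray] = field(default=None, repr=False)  # type: ignore[assignment]
    _adj_dist: list[np.ndarray] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.edge_dist = np.asarray(self.edge_dist, dtype=float)
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        if self._adj is None:
            self._build_adjacency()

    def _build_adjacency(self) -> None:
        n = len(self.ids)
        nbrs: list[list[int]] = [[] for _ in range(n)]
        dists: list[list[float]] = [[] for _ in range(n)]
        for (u, v), d in zip(self.edges, self.edge_dist):
            nbrs[u].append(v)
            dists[u].append(d)
            nbrs[v].append(u)
            dists[v].append(d)
        self._adj = [np.array(a, dtype=int) for a in nbrs]
        self._adj_dist = [np.array(a, dtype=float) for a in dists]

    @property
    def n_vertices(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_dist)

    def neighbors(self, u: int) -> tuple[np.ndarray, np.ndarray]:
        """(neighbor indices, edge distances) of vertex index u."""
        return self._adj[u], self._adj_dist[u]

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def adjacency_sparse(self) -> csr_matrix:
        n = self.n_vertices
        if self.n_edges == 0:
            return csr_matrix((n, n))
        u, v = self.edges[:, 0], self.edges[:, 1]
        row = np.concatenate([u, v])
        col = np.concatenate([v, u])
        dat = np.concatenate([self.edge_dist, self.edge_dist])
        return csr_matrix((dat, (row, col)), shape=(n, n))

    def component_labels(self) -> np.ndarray:
        n_comp, labels = connected_components(
            self.adjacency_sparse(), directed=False
        )
        return labels

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_weighted_edges_from(
            (int(u), int(v), float(d))
            for (u, v), d in zip(self.edges, self.edge_dist)
        )
        return g

    def export(self, out_dir: str | Path, stem: str = "nn_graph") -> tuple[Path, Path]:
        """Edge-list TSV (u, v, distance by id) plus a JSON header."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        edge_path = out_dir / f"{stem}_edges.tsv"
        with edge_path.open("w") as fh:
            fh.write("u\tv\tdistance\n")
            for (u, v), d in zip(self.edges, self.edge_dist):
                fh.write(f"{self.ids[u]}\t{self.ids[v]}\t{d:.6f}\n")
        head_path = out_dir / f"{stem}_header.json"
        head_path.write_text(
            json.dumps(
                {
                    "epsilon_used": self.epsilon_used,
                    "connected": self.connected,
                    "n": self.n_vertices,
                    "m": self.n_edges,
                },
                indent=2,
            )
        )
        return edge_path, head_path


def _is_connected(mask: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(mask), directed=False)
    return n_comp == 1


def build_nn_graph(
    distances: DistanceStore,
    epsilon0: float = 1.0,
    max_iter: int = 10,
    eps_step: float = 0.5,
    max_nn: int = 100,
) -> NNGraph:
    """Build the epsilon nn-graph, growing epsilon until connected.

    Starting from ``epsilon0`` (1 A by default), the threshold grows by
    ``eps_step`` per iteration, at most ``max_iter`` times, while the graph
    is disconnected. Each vertex then keeps at most ``max_nn`` nearest
    neighbors (ascending distance, ties by id); an edge survives the cap only
    if both endpoints keep it, so the graph stays undirected. If the graph is
    still disconnected after the growth budget it is returned with
    ``connected=False`` and downstream stages operate per component.
    """
    n = len(distances)
    if n < 2:
        raise ValueError("need at least 2 decoys to build a graph")
    D = distances.matrix
    eye = np.eye(n, dtype=bool)

    eps = float(epsilon0)
    mask = (D <= eps) & ~eye
    grown = 0
    while not _is_connected(mask) and grown < max_iter:
        eps += eps_step
        grown += 1
        mask = (D <= eps) & ~eye

    # Per-vertex neighbor cap: ties broken by (distance, id) lexicographically.
    id_rank = np.argsort(np.argsort(np.array(distances.ids, dtype=object)))
    kept = np.zeros_like(mask)
    for u in range(n):
        nbr = np.flatnonzero(mask[u])
        if len(nbr) > max_nn:
            order = np.lexsort((id_rank[nbr], D[u, nbr]))
            nbr = nbr[order[:max_nn]]
        kept[u, nbr] = True
    mutual = kept & kept.T

    iu, iv = np.nonzero(np.triu(mutual, k=1))
    edges = np.stack([iu, iv], axis=1) if len(iu) else np.empty((0, 2), dtype=int)
    edge_dist = D[iu, iv] if len(iu) else np.empty(0)
    connected = _is_connected(mutual)
    if not connected:
        warnings.warn(
            f"nn-graph still disconnected at epsilon={eps:.2f} A; "
            "downstream stages operate per component",
            stacklevel=2,
        )
    return NNGraph(
        ids=list(distances.ids),
        edges=edges,
        edge_dist=edge_dist,
        epsilon_used=eps,
        connected=connected,
    )
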