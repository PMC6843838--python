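"""Basin decomposition of the energy landscape embedded in an nn-graph.

A vertex is a local minimum when its energy is no higher than the energies of
its 1-neighbors; flat plateaus are resolved deterministically with the
lexicographic key (energy, id), so each plateau contributes exactly one
minimum. Every other vertex follows a discrete negative gradient -- the edge
maximizing the steepest ratio [e(u) - e(v)] / d(u, v) -- until it reaches a
local minimum; vertices that reach the same minimum form one basin. Basins
therefore partition the vertex set, with the focal minimum the basin's
lowest-energy member.

Persistence quantifies basin shallowness via sublevel-set filtration with a
union-find: a minimum dies when the growing sublevel set first connects it to
a lexicographically older (deeper) minimum, and its persistence is the energy
gap between that merge and its own level. The surviving minimum of each
connected component gets the component's full energy range so the feature
stays finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .landscape_graph import NNGraph
from .structures_io import DistanceStore

__all__ = [
    "Basin",
    "find_local_minima",
    "assign_basins",
    "compute_persistence",
    "basin_subgraph_components",
    "select_largest_basin",
    "decompose",
    "export_basins",
]


@dataclass
class Basin:
    """A basin of attraction: focal minimum plus the vertices draining to it."""

    focal_id: str
    members: list[str]
    focal_energy: float
    avg_energy: float
    persistence: float | None = None
    n_components: int | None = None
    pareto_rank: int | None = None
    pareto_count: int | None = None
    predicted_purity: float | None = None

    def __post_init__(self) -> None:
        if self.focal_id not in self.members:
            raise ValueError("focal minimum must be a member of its basin")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def min_energy(self) -> float:
        return self.focal_energy

    def group_energy(self, mode: str = "min") -> float:
        if mode == "min":
            return self.focal_energy
        if mode == "avg":
            return self.avg_energy
        raise ValueError(f"unknown group-energy mode {mode!r}")


def _energy_array(graph: NNGraph, energies) -> np.ndarray:
    if isinstance(energies, Mapping):
        arr = np.array([energies[i] for i in graph.ids], dtype=float)
    else:
        arr = np.asarray(energies, dtype=float)
        if arr.shape != (graph.n_vertices,):
            raise ValueError("energies must align with graph vertices")
    if not np.all(np.isfinite(arr)):
        raise ValueError("all energies must be finite")
    return arr


def _id_rank(graph: NNGraph) -> np.ndarray:
    return np.argsort(np.argsort(np.array(graph.ids, dtype=object)))


def find_local_minima(graph: NNGraph, energies) -> set[str]:
    """Vertices minimal under (energy, id) within their closed neighborhood.

    Equivalently: e(u) < e(v) for every neighbor v, or e(u) == e(v) with
    id(u) < id(v) (plateau tie-break). Isolated vertices are minima.
    """
    e = _energy_array(graph, energies)
    rank = _id_rank(graph)
    minima: set[str] = set()
    for u in range(graph.n_vertices):
        nbr, _ = graph.neighbors(u)
        if len(nbr) == 0:
            minima.add(graph.ids[u])
            continue
        ku = (e[u], rank[u])
        if all(ku < (e[v], rank[v]) for v in nbr):
            minima.add(graph.ids[u])
    return minima


def _descent_targets(graph: NNGraph, e: np.ndarray, rank: np.ndarray) -> np.ndarray:
    """Per-vertex next hop of the steepest-ratio descent (-1 for minima)."""
    nxt = np.full(graph.n_vertices, -1, dtype=int)
    for u in range(graph.n_vertices):
        nbr, dist = graph.neighbors(u)
        if len(nbr) == 0:
            continue
        ku = (e[u], rank[u])
        if all(ku < (e[v], rank[v]) for v in nbr):
            continue  # local minimum
        ratios = (e[u] - e[nbr]) / np.maximum(dist, 1e-300)
        ties = nbr[ratios == ratios.max()]  # ties by smaller id
        nxt[u] = ties[np.argmin(rank[ties])]
    return nxt


def assign_basins(graph: NNGraph, energies) -> list[Basin]:
    """Partition the vertices into basins by steepest-ratio descent.

    Returned basins are sorted by (focal energy, focal id).
    """
    e = _energy_array(graph, energies)
    rank = _id_rank(graph)
    nxt = _descent_targets(graph, e, rank)

    n = graph.n_vertices
    root = np.full(n, -1, dtype=int)

    def resolve(u: int) -> int:
        path = []
        while root[u] < 0 and nxt[u] >= 0:
            path.append(u)
            u = nxt[u]
            if len(path) > n:
                raise RuntimeError(
                    "descent cycle detected -- internal consistency failure"
                )
        r = root[u] if root[u] >= 0 else u
        for p in path:
            root[p] = r
        root[u] = r
        return r

    for u in range(n):
        resolve(u)

    groups: dict[int, list[int]] = {}
    for u in range(n):
        groups.setdefault(int(root[u]), []).append(u)

    basins = []
    for focal, members in groups.items():
        if e[focal] != min(e[m] for m in members):  # pragma: no cover
            raise RuntimeError("focal minimum is not the basin energy minimum")
        basins.append(
            Basin(
                focal_id=graph.ids[focal],
                members=sorted((graph.ids[m] for m in members)),
                focal_energy=float(e[focal]),
                avg_energy=float(np.mean([e[m] for m in members])),
            )
        )
    basins.sort(key=lambda b: (b.focal_energy, b.focal_id))
    return basins


def compute_persistence(graph: NNGraph, energies, minima: set[str]) -> dict[str, float]:
    """Sublevel-set persistence of each local minimum, by union-find.

    Vertices enter in ascending (energy, id); when a vertex joins two
    components the one whose minimum is lexicographically younger dies with
    persistence = current energy - its focal energy. The surviving minimum of
    each graph component receives (component max energy - focal energy).
    """
    e = _energy_array(graph, energies)
    rank = _id_rank(graph)
    n = graph.n_vertices
    order = np.lexsort((rank, e))
    idx_of = {i: k for k, i in enumerate(graph.ids)}
    min_idx = {idx_of[m] for m in minima}

    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # component representative -> index of its oldest (lexic. smallest) minimum
    comp_min: dict[int, int] = {}
    persistence: dict[str, float] = {}
    active = np.zeros(n, dtype=bool)

    for u in order:
        active[u] = True
        comp_min[u] = u if u in min_idx else -1
        nbr, _ = graph.neighbors(u)
        for v in nbr:
            if not active[v]:
                continue
            ru, rv = find(u), find(v)
            if ru == rv:
                continue
            mu, mv = comp_min[ru], comp_min[rv]
            # merge: keep the lexicographically older minimum alive
            if mu == -1:
                keep, die = mv, -1
            elif mv == -1:
                keep, die = mu, -1
            elif (e[mu], rank[mu]) <= (e[mv], rank[mv]):
                keep, die = mu, mv
            else:
                keep, die = mv, mu
            if die != -1:
                persistence[graph.ids[die]] = float(e[u] - e[die])
            parent[rv] = ru
            comp_min[find(ru)] = keep

    # survivors: one per connected component
    labels = graph.component_labels()
    for comp in np.unique(labels):
        verts = np.flatnonzero(labels == comp)
        comp_minima = [v for v in verts if v in min_idx]
        survivor = min(comp_minima, key=lambda v: (e[v], rank[v]))
        persistence[graph.ids[survivor]] = float(e[verts].max() - e[survivor])
    return persistence


def basin_subgraph_components(basin: Basin, distances: DistanceStore) -> int:
    """Connected components of the nn-graph encoding only the basin's members.

    The threshold is pdist + 1 A, with pdist the mean pairwise RMSD between
    the basin's decoys; no epsilon growth and no neighbor cap apply here.
    """
    if basin.size == 1:
        return 1
    D = distances.submatrix(basin.members)
    m = D.shape[0]
    iu = np.triu_indices(m, k=1)
    pdist = float(D[iu].mean())
    eps = pdist + 1.0
    mask = (D <= eps) & ~np.eye(m, dtype=bool)
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(csr_matrix(mask), directed=False)
    return int(n_comp)


def select_largest_basin(basins: Sequence[Basin]) -> Basin:
    """Largest basin; ties by lower focal energy, then focal id."""
    if not basins:
        raise ValueError("no basins to select from")
    return min(basins, key=lambda b: (-b.size, b.focal_energy, b.focal_id))


def decompose(
    graph: NNGraph,
    energies,
    distances: DistanceStore | None = None,
    with_persistence: bool = True,
    with_components: bool = True,
) -> list[Basin]:
    """Full decomposition: basins plus persistence and component features."""
    basins = assign_basins(graph, energies)
    if with_persistence:
        minima = {b.focal_id for b in basins}
        pers = compute_persistence(graph, energies, minima)
        for b in basins:
            b.persistence = pers[b.focal_id]
    if with_components and distances is not None:
        for b in basins:
            b.n_components = basin_subgraph_components(b, distances)
    return basins


def export_basins(basins: Sequence[Basin], out_dir: str | Path, stem: str = "basins") -> tuple[Path, Path]:
    """Basin report: JSON per basin, plus a flat decoy-to-basin TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = [
        {
            "focal_id": b.focal_id,
            "size": b.size,
            "focal_energy": b.focal_energy,
            "avg_energy": b.avg_energy,
            "persistence": b.persistence,
            "n_components": b.n_components,
            "pareto_rank": b.pareto_rank,
            "pareto_count": b.pareto_count,
            "members": b.members,
        }
        for b in basins
    ]
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(report, indent=2))
    tsv_path = out_dir / f"{stem}_membership.tsv"
    with tsv_path.open("w") as fh:
        fh.write("decoy_id\tbasin_focal_id\n")
        for b in basins:
            for m in b.members:
                fh.write(f"{m}\t{b.focal_id}\n")
    return json_path, tsv_path
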