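"""Shared fixtures: tiny programmatic ensembles, graphs, and random instances."""

from __future__ import annotations

import numpy as np
import pytest

from basinselect.landscape_graph import NNGraph
from basinselect.structures_io import Decoy, DecoyEnsemble, DistanceStore


def make_graph(ids, edge_list, epsilon=1.0):
    """NNGraph from [(u_id, v_id, dist), ...] triples."""
    index = {i: k for k, i in enumerate(ids)}
    edges = np.array([[index[u], index[v]] for u, v, _ in edge_list]).reshape(-1, 2)
    dists = np.array([d for _, _, d in edge_list], dtype=float)
    return NNGraph(
        ids=list(ids), edges=edges, edge_dist=dists,
        epsilon_used=epsilon, connected=True,
    )


def random_graph_instance(rng, n_max=60, p=0.15):
    """Random connected-ish weighted graph with random energies."""
    n = int(rng.integers(5, n_max + 1))
    ids = [f"v{i:03d}" for i in range(n)]
    edge_list = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edge_list.append((ids[i], ids[j], float(rng.uniform(0.1, 2.0))))
    # a random spanning path keeps most vertices non-isolated
    perm = rng.permutation(n)
    for a, b in zip(perm[:-1], perm[1:]):
        if not any({ids[a], ids[b]} == {u, v} for u, v, _ in edge_list):
            edge_list.append((ids[a], ids[b], float(rng.uniform(0.1, 2.0))))
    energies = {i: float(rng.normal(0.0, 3.0)) for i in ids}
    # occasional exact plateaus exercise the tie-break rules
    if n >= 10:
        flat = rng.choice(n, size=3, replace=False)
        for f in flat[1:]:
            energies[ids[f]] = energies[ids[flat[0]]]
    return ids, edge_list, energies


def toy_coords(rng, n_res=10):
    return rng.normal(scale=5.0, size=(n_res, 3))


def make_ensemble(rng, n_decoys=6, n_res=8, with_potentials=False, with_native=False):
    """Small random ensemble; energies random, ids in order."""
    native = toy_coords(rng, n_res)
    decoys = []
    for i in range(n_decoys):
        coords = native + rng.normal(scale=0.5 + i * 0.3, size=(n_res, 3))
        decoys.append(
            Decoy(
                id=f"d{i}",
                coords=coords,
                energy=float(rng.normal()),
                potentials=rng.normal(size=4) if with_potentials else None,
            )
        )
    return DecoyEnsemble(
        target_id="toy",
        decoys=decoys,
        native=native if with_native else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def path_graph_5():
    """Path v1-v2-v3-v4-v5 with unit edges and energies (5, 3, 4, 2, 1)."""
    ids = [f"v{i}" for i in range(1, 6)]
    edges = [(ids[i], ids[i + 1], 1.0) for i in range(4)]
    energies = dict(zip(ids, [5.0, 3.0, 4.0, 2.0, 1.0]))
    return make_graph(ids, edges), energies


@pytest.fixture
def small_ensemble(rng):
    return make_ensemble(rng)


@pytest.fixture
def store_from_points():
    """Euclidean DistanceStore factory from an (n, d) point array."""
    from scipy.spatial.distance import pdist, squareform

    def build(points, ids=None):
        points = np.asarray(points, dtype=float)
        ids = ids or [f"p{i}" for i in range(len(points))]
        return DistanceStore(ids, squareform(pdist(points)))

    return build
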