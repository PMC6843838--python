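"""Energy-blind grouping baselines: k-means selection and Louvain communities.

Both baselines group decoys purely by geometry and offer the largest group
for prediction. For k-means, decoys are vectorized by Kabsch-superposing
every decoy onto the first and flattening the C-alpha coordinates, so the
Euclidean metric approximates pairwise RMSD (times sqrt of the residue
count). The number of clusters is picked at the knee of the SSE curve, and
for each k the best of several random-centroid restarts (by within-cluster
scatter) is retained. The community baseline runs Louvain modularity
optimization on the unweighted epsilon nn-graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .landscape_graph import NNGraph
from .structures_io import DecoyEnsemble, kabsch_superpose

__all__ = [
    "ClusterSet",
    "superposed_vectors",
    "kmeans_group",
    "knee_select_k",
    "kmeans_select",
    "community_select",
    "export_clusters",
]


@dataclass
class ClusterSet:
    """A partition of decoy ids with the k-means bookkeeping attached."""

    method: str
    clusters: list[list[str]]
    chosen_k: int
    loss: float | None = None
    sse_curve: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.chosen_k != len(self.clusters):
            raise ValueError("chosen_k must equal the number of clusters")

    def largest(self, energies: Mapping[str, float] | None = None) -> list[str]:
        """Largest cluster; ties by lower mean energy, then first member id."""
        def key(c: list[str]):
            mean_e = (
                float(np.mean([energies[i] for i in c]))
                if energies is not None
                else 0.0
            )
            return (-len(c), mean_e, min(c))

        return sorted(min(self.clusters, key=key))


def export_clusters(cluster_set: ClusterSet, out_dir, stem: str = "clusters"):
    """Cluster report mirroring the basin report: JSON + membership TSV."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "method": cluster_set.method,
        "chosen_k": cluster_set.chosen_k,
        "loss": cluster_set.loss,
        "sse_curve": cluster_set.sse_curve,
        "clusters": [
            {"cluster": i, "size": len(c), "members": list(c)}
            for i, c in enumerate(cluster_set.clusters)
        ],
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(report, indent=2))
    tsv_path = out_dir / f"{stem}_membership.tsv"
    with tsv_path.open("w") as fh:
        fh.write("decoy_id\tcluster\n")
        for i, c in enumerate(cluster_set.clusters):
            for m in c:
                fh.write(f"{m}\t{i}\n")
    return json_path, tsv_path


def superposed_vectors(ensemble: DecoyEnsemble) -> np.ndarray:
    """(size, 3 * n_res) matrix: each decoy superposed onto the first, flattened."""
    ref = ensemble.decoys[0].coords
    rows = [ref - ref.mean(axis=0)]
    for d in ensemble.decoys[1:]:
        rows.append(kabsch_superpose(d.coords, rows[0]))
    return np.stack([r.ravel() for r in rows])


def _within_cluster_scatter(X: np.ndarray, labels: np.ndarray) -> float:
    """L(C) = 1/2 sum over clusters of all ordered within-cluster distances."""
    total = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        if len(members) > 1:
            total += float(pdist(members).sum())  # = 1/2 of ordered pairs
    return total


def _sse(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        centroid = members.mean(axis=0)
        total += float(np.sum((members - centroid) ** 2))
    return total


def _kmeans_best_restart(
    X: np.ndarray, k: int, n_restarts: int, rng: np.random.Generator
) -> tuple[np.ndarray, float, float]:
    """Best-of-restarts k-means on a data matrix.

    Each restart initializes the centroids with k decoys drawn uniformly at
    random; the restart minimizing the within-cluster scatter L(C) is kept.
    Returns (labels, loss, sse).
    """
    n = X.shape[0]
    best = None
    seen: set[bytes] = set()
    for _ in range(n_restarts):
        init_idx = rng.choice(n, size=k, replace=False)
        km = KMeans(n_clusters=k, init=X[init_idx], n_init=1, max_iter=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate init points etc.
            labels = km.fit_predict(X)
        key = labels.tobytes()
        if key in seen:
            continue  # identical partition: same loss, skip the O(n^2) scan
        seen.add(key)
        loss = _within_cluster_scatter(X, labels)
        if best is None or loss < best[1]:
            best = (labels, loss, _sse(X, labels))
    assert best is not None
    return best


def kmeans_group(
    ensemble: DecoyEnsemble,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    vectors: np.ndarray | None = None,
) -> ClusterSet:
    """Group decoys with k-means, retaining the best of ``n_restarts`` restarts."""
    if not 1 <= k <= ensemble.size:
        raise ValueError(f"k={k} outside [1, {ensemble.size}]")
    X = superposed_vectors(ensemble) if vectors is None else vectors
    rng = np.random.default_rng(seed)
    labels, loss, sse = _kmeans_best_restart(X, k, n_restarts, rng)
    ids = np.array(ensemble.ids, dtype=object)
    clusters = [sorted(ids[labels == lab]) for lab in np.unique(labels)]
    return ClusterSet(
        method="kmeans",
        clusters=clusters,
        chosen_k=len(clusters),
        loss=loss,
        sse_curve={k: sse},
    )


def _knee_from_curve(ks: np.ndarray, sse: np.ndarray) -> int:
    """k maximizing perpendicular distance to the chord of the SSE curve."""
    x1, y1 = ks[0], sse[0]
    x2, y2 = ks[-1], sse[-1]
    span = np.hypot(x2 - x1, y2 - y1)
    if span == 0 or np.isclose(sse.max(), sse.min()):
        warnings.warn("SSE curve is flat; returning k=1", stacklevel=3)
        return 1
    dist = np.abs((y2 - y1) * ks - (x2 - x1) * sse + x2 * y1 - y2 * x1) / span
    if np.allclose(dist, 0.0):
        warnings.warn("SSE curve has no curvature; returning k=1", stacklevel=3)
        return 1
    return int(ks[int(np.argmax(dist))])  # argmax: ties resolve to smaller k


def knee_select_k(
    ensemble: DecoyEnsemble,
    k_max: int = 25,
    n_restarts: int = 10,
    seed: int = 0,
    vectors: np.ndarray | None = None,
    return_curve: bool = False,
):
    """Optimal k at the knee (max distance to chord) of the SSE-vs-k curve."""
    if not 2 <= k_max < ensemble.size:
        raise ValueError(f"k_max={k_max} outside [2, {ensemble.size - 1}]")
    X = superposed_vectors(ensemble) if vectors is None else vectors
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    sse = np.empty(len(ks))
    for j, k in enumerate(ks):
        _, _, sse[j] = _kmeans_best_restart(X, int(k), n_restarts, rng)
    knee = _knee_from_curve(ks, sse)
    if return_curve:
        return knee, dict(zip(ks.tolist(), sse.tolist()))
    return knee


def kmeans_select(
    ensemble: DecoyEnsemble,
    k_max: int = 25,
    n_restarts: int = 10,
    seed: int = 0,
    return_clusters: bool = False,
):
    """Largest k-means cluster at the knee-selected k (the k-means baseline)."""
    X = superposed_vectors(ensemble)
    knee, curve = knee_select_k(
        ensemble, k_max=k_max, n_restarts=n_restarts, seed=seed,
        vectors=X, return_curve=True,
    )
    grouping = kmeans_group(
        ensemble, knee, n_restarts=n_restarts, seed=seed, vectors=X
    )
    grouping.sse_curve = curve
    energies = dict(zip(ensemble.ids, ensemble.energies()))
    selected = grouping.largest(energies)
    if return_clusters:
        return selected, grouping
    return selected


def community_select(
    graph: NNGraph,
    seed: int = 0,
    energies: Mapping[str, float] | None = None,
    resolution: float = 1.0,
    return_clusters: bool = False,
):
    """Largest Louvain community of the nn-graph (the community baseline).

    Modularity is optimized on the unweighted graph with a seeded vertex
    order. An edgeless graph makes every vertex its own community; a single
    vertex is then returned with a warning.
    """
    import networkx as nx

    g = graph.to_networkx()
    if graph.n_edges == 0:
        warnings.warn(
            "graph has no edges; every vertex is its own community",
            stacklevel=2,
        )
        communities = [{u} for u in range(graph.n_vertices)]
    else:
        communities = nx.community.louvain_communities(
            g, weight=None, resolution=resolution, seed=int(seed)
        )
    clusters = [sorted(graph.ids[u] for u in c) for c in communities]
    cluster_set = ClusterSet(
        method="louvain", clusters=clusters, chosen_k=len(clusters)
    )
    selected = cluster_set.largest(energies)
    if return_clusters:
        return selected, cluster_set
    return selected
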