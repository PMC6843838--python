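"""Independent reference implementations used as test oracles.

Each oracle takes the most literal, brute-force route to its quantity and
shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Least RMSD via the quaternion characteristic-eigenvalue method.

    The optimal superposition score is the largest eigenvalue of the 4x4 key
    matrix built from the cross-covariance of the centered coordinates; this
    formulation never constructs a rotation matrix and cannot produce a
    reflection, making it an independent check on Kabsch-based paths.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    ga = float(np.sum(A * A))
    gb = float(np.sum(B * B))
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = float(np.linalg.eigvalsh(K)[-1])
    msd = (ga + gb - 2.0 * lam) / len(A)
    return float(np.sqrt(max(msd, 0.0)))


def _adjacency(ids, edges, dists):
    adj: dict[str, list[tuple[str, float]]] = {i: [] for i in ids}
    for (u, v), d in zip(edges, dists):
        adj[ids[u]].append((ids[v], d))
        adj[ids[v]].append((ids[u], d))
    return adj


def closed_neighborhood_minima(ids, edges, dists, energies) -> set[str]:
    """Local minima by exhaustive closed-neighborhood comparison of (energy, id)."""
    adj = _adjacency(ids, edges, dists)
    out = set()
    for u in ids:
        if all((energies[u], u) < (energies[v], v) for v, _ in adj[u]):
            out.add(u)
    return out


def descent_partition(ids, edges, dists, energies) -> dict[str, str]:
    """Map each vertex to its basin's focal minimum by literal path following.

    Every step re-evaluates the steepest ratio [e(u) - e(v)] / d(u, v) over
    the current vertex's neighbors (ties to the smaller id), with no
    memoization across vertices.
    """
    adj = _adjacency(ids, edges, dists)
    minima = closed_neighborhood_minima(ids, edges, dists, energies)

    def step(u: str) -> str:
        best_ratio, best_id = None, None
        for v, d in adj[u]:
            ratio = (energies[u] - energies[v]) / d
            if best_ratio is None or ratio > best_ratio or (
                ratio == best_ratio and v < best_id
            ):
                best_ratio, best_id = ratio, v
        return best_id

    out = {}
    for u in ids:
        cur = u
        steps = 0
        while cur not in minima:
            cur = step(cur)
            steps += 1
            assert steps <= len(ids), "descent did not terminate"
        out[u] = cur
    return out


def persistence_sweep(ids, edges, dists, energies) -> dict[str, float]:
    """Sublevel persistence by exhaustive component scans at every level.

    Vertices are added one at a time in ascending (energy, id); after each
    addition the induced subgraph's components are recomputed from scratch.
    A minimum dies at the first level where its component contains a
    lexicographically older minimum; survivors get their full component
    energy range.
    """
    adj = _adjacency(ids, edges, dists)
    minima = closed_neighborhood_minima(ids, edges, dists, energies)
    order = sorted(ids, key=lambda u: (energies[u], u))

    def components(active: set[str]) -> list[set[str]]:
        seen, comps = set(), []
        for s in active:
            if s in seen:
                continue
            comp, stack = set(), [s]
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(v for v, _ in adj[x] if v in active and v not in comp)
            seen |= comp
            comps.append(comp)
        return comps

    dead: dict[str, float] = {}
    active: set[str] = set()
    for u in order:
        active.add(u)
        for comp in components(active):
            mins_here = sorted(
                (m for m in comp if m in minima and m not in dead),
                key=lambda m: (energies[m], m),
            )
            for younger in mins_here[1:]:
                dead[younger] = energies[u] - energies[younger]
    for comp in components(set(ids)):
        survivor = min(
            (m for m in comp if m in minima),
            key=lambda m: (energies[m], m),
        )
        dead[survivor] = max(energies[v] for v in comp) - energies[survivor]
    return dead


def dominance_counts(sizes, energies) -> tuple[np.ndarray, np.ndarray]:
    """(rank, count) per basin by a literal double loop over the dominance rule."""
    n = len(sizes)
    rank = np.zeros(n, dtype=int)
    count = np.zeros(n, dtype=int)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            better_or_equal = sizes[a] >= sizes[b] and energies[a] <= energies[b]
            strict = sizes[a] > sizes[b] or energies[a] < energies[b]
            if better_or_equal and strict:
                count[a] += 1
                rank[b] += 1
    return rank, count


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_modularity_partition(graph_nx):
    """Exhaustive modularity maximization over all partitions (small graphs)."""
    import networkx as nx

    nodes = list(graph_nx.nodes)
    best_q, best_part = -np.inf, None
    for part in _set_partitions(nodes):
        q = nx.community.modularity(graph_nx, [set(p) for p in part])
        if q > best_q:
            best_q, best_part = q, [set(p) for p in part]
    return best_part, best_q
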