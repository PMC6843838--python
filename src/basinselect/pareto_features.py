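"""Pareto dominance features over basins: rank and count.

Basins are compared on (size, group energy): basin a dominates basin b when
a is at least as large and at least as low in energy, strictly better in at
least one of the two. A basin's Pareto Rank is the number of basins that
dominate it (0 for the non-dominated front) and its Pareto Count the number
of basins it dominates. These are the Phase-1 purity-regression features.

The rank can alternatively be computed as the front-peeling level (0 for the
first non-dominated front, 1 for the front after removing it, ...); the
dominator-count scheme is the default as it is monotone with front level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .basin_decomposition import Basin

__all__ = ["ParetoAnnotation", "pareto_annotate", "dominates"]


@dataclass
class ParetoAnnotation:
    """Per-basin dominance features, aligned with the input basin order."""

    pareto_rank: np.ndarray
    pareto_count: np.ndarray
    group_energy_mode: str
    rank_scheme: str


def dominates(size_a: int, e_a: float, size_b: int, e_b: float) -> bool:
    """True when (size_a, e_a) dominates (size_b, e_b): bigger and lower-energy."""
    return (
        size_a >= size_b
        and e_a <= e_b
        and (size_a > size_b or e_a < e_b)
    )


def _front_levels(sizes: np.ndarray, energies: np.ndarray) -> np.ndarray:
    n = len(sizes)
    level = np.full(n, -1, dtype=int)
    remaining = set(range(n))
    current = 0
    while remaining:
        front = [
            b
            for b in remaining
            if not any(
                dominates(sizes[a], energies[a], sizes[b], energies[b])
                for a in remaining
                if a != b
            )
        ]
        for b in front:
            level[b] = current
        remaining -= set(front)
        current += 1
    return level


def pareto_annotate(
    basins: Sequence[Basin],
    energy_mode: str = "min",
    rank_scheme: str = "dominators",
) -> ParetoAnnotation:
    """Annotate basins in place with Pareto rank and count; returns the arrays.

    ``energy_mode`` picks the basin group energy (focal minimum by default,
    or the member average). ``rank_scheme`` is ``"dominators"`` (rank = how
    many basins dominate this one) or ``"front"`` (front-peeling level); the
    count is the number of dominated basins in either scheme.
    """
    if not basins:
        raise ValueError("need at least one basin")
    if rank_scheme not in ("dominators", "front"):
        raise ValueError(f"unknown rank scheme {rank_scheme!r}")
    sizes = np.array([b.size for b in basins], dtype=int)
    energies = np.array([b.group_energy(energy_mode) for b in basins], dtype=float)
    n = len(basins)
    dom = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(n):
            if a != b and dominates(sizes[a], energies[a], sizes[b], energies[b]):
                dom[a, b] = True
    count = dom.sum(axis=1)
    if rank_scheme == "dominators":
        rank = dom.sum(axis=0)
    else:
        rank = _front_levels(sizes, energies)
    for b, r, c in zip(basins, rank, count):
        b.pareto_rank = int(r)
        b.pareto_count = int(c)
    return ParetoAnnotation(
        pareto_rank=rank.astype(int),
        pareto_count=count.astype(int),
        group_energy_mode=energy_mode,
        rank_scheme=rank_scheme,
    )
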