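"""Weighted selection of a single decoy from a basin.

Two weighting schemes are supported. The predicted-RMSD scheme sets
w_i = 1 / (rmsd_i + zeta), a non-increasing non-negative function of the
decoy's predicted distance to the native, so closer-looking decoys carry
more weight. The density scheme computes each decoy's mean pairwise RMSD to
the rest of its basin, normalizes those scores into [-1, 1] about the median,
and sets w_i = exp(-k * S'_i); outlier decoys (large mean distance) receive
exponentially less weight. Normalized weights define the probability p_i of
drawing each decoy, and the weighted purity of a basin,
wp(B) = sum w_i g_i / sum w_i, is exactly the probability of drawing a
near-native (g_i = 1) decoy under p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .structures_io import DistanceStore

__all__ = [
    "WeightVector",
    "DensityScores",
    "density_scores",
    "weights_from_density",
    "weights_from_predicted_rmsd",
    "weighted_purity",
    "select_decoy",
    "random_select",
]


@dataclass
class WeightVector:
    """Per-decoy weights over a basin's members, with selection probabilities."""

    ids: list[str]
    weights: np.ndarray
    scheme: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.ids):
            raise ValueError("one weight per decoy id required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def probabilities(self) -> np.ndarray:
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("all-zero weights cannot be normalized")
        return self.weights / total

    def export_tsv(self, path: str | Path) -> None:
        p = self.probabilities
        with Path(path).open("w") as fh:
            fh.write("id\tw\tp\tscheme\n")
            for i, w, pi in zip(self.ids, self.weights, p):
                fh.write(f"{i}\t{w:.8g}\t{pi:.8g}\t{self.scheme}\n")


@dataclass
class DensityScores:
    """Raw and median-normalized density scores of a basin's members."""

    ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    s_min: float
    s_max: float
    s_median: float


def density_scores(members: Sequence[str], distances: DistanceStore) -> DensityScores:
    """Density score S_i = (sum_{j != i} r_ij) / m over the basin members.

    Normalization is piecewise about the median: scores below it are scaled
    by (S_med - S_min), above it by (S_max - S_med), mapping the extremes to
    -1 and +1 and the median to 0. A degenerate denominator (all scores on
    one side equal) sends that branch to 0, so an all-equal basin normalizes
    to all zeros.
    """
    m = len(members)
    if m < 2:
        raise ValueError("density scores need at least 2 members")
    D = distances.submatrix(members)
    raw = D.sum(axis=1) / m
    s_min, s_max, s_med = float(raw.min()), float(raw.max()), float(np.median(raw))
    norm = np.zeros(m)
    lo, hi = s_med - s_min, s_max - s_med
    below = raw < s_med
    above = raw > s_med
    if lo > 0:
        norm[below] = (raw[below] - s_med) / lo
    if hi > 0:
        norm[above] = (raw[above] - s_med) / hi
    return DensityScores(
        ids=list(members),
        raw=raw,
        normalized=norm,
        s_min=s_min,
        s_max=s_max,
        s_median=s_med,
    )


def weights_from_density(scores: DensityScores, k: float = 5.0) -> WeightVector:
    """w_i = exp(-k * S'_i): low-density (outlier) decoys are down-weighted."""
    return WeightVector(
        ids=list(scores.ids),
        weights=np.exp(-k * scores.normalized),
        scheme="density",
        params={"k": k},
    )


def weights_from_predicted_rmsd(
    ids: Sequence[str],
    predicted: Sequence[float],
    zeta: float = 1e-6,
) -> WeightVector:
    """w_i = 1 / (predicted_i + zeta); zeta guards against division by zero."""
    predicted = np.asarray(predicted, dtype=float)
    if np.any(predicted < 0):
        raise ValueError("predicted RMSDs must be non-negative")
    return WeightVector(
        ids=list(ids),
        weights=1.0 / (predicted + zeta),
        scheme="predicted_rmsd",
        params={"zeta": zeta},
    )


def weighted_purity(weights: WeightVector, goodness: Mapping[str, int] | Sequence[int]) -> float:
    """wp(B) = sum w_i g_i / sum w_i, with g_i = 1 iff decoy i is near-native."""
    if isinstance(goodness, Mapping):
        g = np.array([goodness[i] for i in weights.ids], dtype=float)
    else:
        g = np.asarray(goodness, dtype=float)
        if len(g) != len(weights.ids):
            raise ValueError("goodness must align with the weight vector")
    total = weights.weights.sum()
    if total <= 0:
        raise ValueError("all-zero weights")
    return float(np.dot(weights.weights, g) / total)


def select_decoy(
    weights: WeightVector, energies: Mapping[str, float] | None = None
) -> str:
    """Highest-weight decoy; ties by lower energy, then id."""
    w = weights.weights
    top = np.flatnonzero(w == w.max())
    candidates = [weights.ids[i] for i in top]
    if energies is not None:
        return min(candidates, key=lambda i: (energies[i], i))
    return min(candidates)


def random_select(members: Sequence[str], n_draws: int = 10, seed: int = 0) -> list[str]:
    """Uniform draws with replacement from a basin (the random baseline)."""
    if not members:
        raise ValueError("cannot draw from an empty basin")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(members), size=n_draws)
    return [members[i] for i in idx]
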