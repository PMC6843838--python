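"""Ground-truth labeling, difficulty categorization, and selection metrics.

With the native structure in hand, every decoy gets a goodness label:
near-native iff its least RMSD to the native is strictly under dist_thresh.
The threshold itself depends on the difficulty of the decoy set, which is
governed by min_dist (the best decoy's RMSD) and by near-native scarcity:
easy sets (min_dist < 1 A) use 2 A, medium sets 2.5 A escalating to 3 A when
near-natives are scarce, and hard sets escalate from just above min_dist + 1 A
until at least one near-native exists. A category left with fewer than ten
near-natives at its final threshold moves to the next harder category.

Selected decoy subsets are scored by purity TP(S)/|S|; individually selected
decoys by RMSD loss -- the gap between the selected decoy's RMSD to the
native and the best decoy's.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structures_io import DecoyEnsemble

__all__ = [
    "EvalConfig",
    "SelectionScore",
    "label_near_natives",
    "categorize_difficulty",
    "purity",
    "rmsd_loss",
    "selection_score",
    "ensemble_summary",
    "compare_methods",
    "plot_purity_comparison",
]


@dataclass
class EvalConfig:
    """Evaluation parameters: threshold, purification shift, difficulty rules."""

    dist_thresh: float | None = None  # None: derive from difficulty rules
    tau_frac: float = 0.0
    scarcity_cutoff: int = 10
    escalation_step: float = 0.5

    def __post_init__(self) -> None:
        if self.dist_thresh is not None and self.dist_thresh <= 0:
            raise ValueError("dist_thresh must be positive")


@dataclass
class SelectionScore:
    """Score card for one selected decoy subset."""

    method: str
    purity: float
    size: int
    tp: int
    weighted_purity: float | None = None
    loss: float | None = None


def label_near_natives(
    ensemble: DecoyEnsemble, dist_thresh: float
) -> dict[str, int]:
    """g_i = 1 iff least_rmsd(decoy_i, native) < dist_thresh (strictly under)."""
    if ensemble.native is None:
        raise ValueError("ensemble has no native structure to label against")
    rmsds = ensemble.true_rmsds()
    return {
        d.id: int(r < dist_thresh) for d, r in zip(ensemble.decoys, rmsds)
    }


def _round_up_half(x: float) -> float:
    return math.ceil(x / 0.5) * 0.5


def categorize_difficulty(
    min_dist: float,
    near_native_counter: Callable[[float], int],
    scarcity_cutoff: int = 10,
    escalation_step: float = 0.5,
    max_escalations: int = 50,
) -> tuple[str, float]:
    """Difficulty level and near-native threshold for a decoy set.

    ``near_native_counter`` maps a candidate dist_thresh to the number of
    decoys under it. Easy (min_dist < 1 A) uses 2 A; medium (1 <= min_dist
    < 3 A) uses 2.5 A, escalated to 3 A when fewer than ``scarcity_cutoff``
    near-natives exist; hard starts at min_dist + 1 A rounded up to the next
    half angstrom and escalates until at least one near-native exists. Easy
    and medium sets still scarce at their final threshold move to the next
    harder category.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be non-negative")

    def hard_rules() -> tuple[str, float]:
        thresh = _round_up_half(min_dist + 1.0)
        for _ in range(max_escalations):
            if near_native_counter(thresh) >= 1:
                return "hard", thresh
            thresh += escalation_step
        warnings.warn(
            "hard-category escalation exhausted without a near-native",
            stacklevel=3,
        )
        return "hard", thresh

    def medium_rules() -> tuple[str, float]:
        if near_native_counter(2.5) >= scarcity_cutoff:
            return "medium", 2.5
        if near_native_counter(3.0) >= scarcity_cutoff:
            return "medium", 3.0
        return hard_rules()

    if min_dist < 1.0:
        if near_native_counter(2.0) >= scarcity_cutoff:
            return "easy", 2.0
        return medium_rules()
    if min_dist < 3.0:
        return medium_rules()
    return hard_rules()


def purity(selected: Sequence[str], goodness: Mapping[str, int]) -> float:
    """TP(S)/|S|: fraction of near-native decoys in the selected set."""
    if not selected:
        raise ValueError("cannot score an empty selection")
    return float(np.mean([goodness[i] for i in selected]))


def rmsd_loss(selected_id: str, ensemble: DecoyEnsemble) -> float:
    """RMSD(selected, native) - RMSD(best decoy, native); zero iff best."""
    rmsds = ensemble.true_rmsds()
    sel = ensemble[selected_id].true_rmsd
    return float(sel - rmsds.min())


def selection_score(
    method: str, selected: Sequence[str], goodness: Mapping[str, int]
) -> SelectionScore:
    tp = int(sum(goodness[i] for i in selected))
    return SelectionScore(
        method=method, purity=tp / len(selected), size=len(selected), tp=tp
    )


def ensemble_summary(ensemble: DecoyEnsemble) -> dict[str, float]:
    """Dataset context: median RMSD, % under 3 A, % under min_dist + 1.5 A."""
    rmsds = ensemble.true_rmsds()
    return {
        "median_rmsd": float(np.median(rmsds)),
        "pct_below_3A": float(np.mean(rmsds < 3.0) * 100.0),
        "pct_below_mindist_plus_1.5A": float(
            np.mean(rmsds < rmsds.min() + 1.5) * 100.0
        ),
    }


def compare_methods(
    ensemble: DecoyEnsemble,
    library=None,
    seed: int = 0,
    config: EvalConfig | None = None,
    k_max: int = 10,
    n: int = 5,
    l: int = 1,
    n_random_draws: int = 10,
    precomputed=None,
    cache_dir=None,
) -> pd.DataFrame:
    """Run every selection method on one ensemble and score them.

    Rows: KMeans-Select, Community-Select, Basins-Select, ML-Select (with
    weighted purity), the two Weighted-Decoy-Select variants and
    Random-Decoy-Select (average of seeded uniform draws). Purity-based
    methods also report the difference against the KMeans-Select baseline.
    The ML rows require a trained ``ModelLibrary``.
    """
    from .basin_decomposition import select_largest_basin
    from .cluster_baselines import community_select, kmeans_select
    from .ml_select import landscape_decomposition, ml_select_pipeline
    from .weighted_select import (
        density_scores,
        random_select,
        select_decoy,
        weighted_purity,
        weights_from_density,
        weights_from_predicted_rmsd,
    )

    config = config or EvalConfig()
    rmsds = ensemble.true_rmsds()
    if config.dist_thresh is not None:
        level, dist_thresh = "(fixed)", config.dist_thresh
    else:
        level, dist_thresh = categorize_difficulty(
            ensemble.min_dist,
            lambda t: int(np.sum(rmsds < t)),
            scarcity_cutoff=config.scarcity_cutoff,
            escalation_step=config.escalation_step,
        )
    goodness = label_near_natives(ensemble, dist_thresh)
    energies = dict(zip(ensemble.ids, ensemble.energies()))

    if precomputed is None:
        precomputed = landscape_decomposition(ensemble, cache_dir=cache_dir)
    distances, graph, basins = precomputed

    scores: list[SelectionScore] = []

    kmeans_ids = kmeans_select(ensemble, k_max=k_max, seed=seed)
    scores.append(selection_score("KMeans-Select", kmeans_ids, goodness))

    community_ids = community_select(graph, seed=seed, energies=energies)
    scores.append(selection_score("Community-Select", community_ids, goodness))

    largest = select_largest_basin(basins)
    scores.append(selection_score("Basins-Select", largest.members, goodness))

    losses: dict[str, float] = {}
    if library is not None:
        result = ml_select_pipeline(
            ensemble,
            library,
            n=n,
            l=l,
            tau_frac=config.tau_frac,
            seed=seed,
            precomputed=precomputed,
        )
        top = result.top
        ml_score = selection_score("ML-Select", top.kept_ids, goodness)
        w_pred = weights_from_predicted_rmsd(
            top.kept_ids, [top.predicted_rmsd[i] for i in top.kept_ids]
        )
        ml_score.weighted_purity = weighted_purity(w_pred, goodness)
        scores.append(ml_score)

        pick_pred = select_decoy(w_pred, energies)
        losses["Weighted-Decoy-Select (predicted-rmsd)"] = rmsd_loss(
            pick_pred, ensemble
        )
        if top.size >= 2:
            w_dens = weights_from_density(density_scores(top.kept_ids, distances))
        else:
            w_dens = w_pred  # a singleton basin has no density structure
        pick_dens = select_decoy(w_dens, energies)
        losses["Weighted-Decoy-Select (density)"] = rmsd_loss(
            pick_dens, ensemble
        )
        draws = random_select(top.kept_ids, n_draws=n_random_draws, seed=seed)
        losses["Random-Decoy-Select"] = float(
            np.mean([rmsd_loss(i, ensemble) for i in draws])
        )

    rows = []
    kmeans_purity = scores[0].purity
    for s in scores:
        rows.append(
            {
                "method": s.method,
                "purity": s.purity,
                "weighted_purity": s.weighted_purity,
                "size": s.size,
                "tp": s.tp,
                "purity_minus_kmeans": s.purity - kmeans_purity,
                "loss": None,
            }
        )
    for name, loss in losses.items():
        rows.append(
            {
                "method": name,
                "purity": None,
                "weighted_purity": None,
                "size": 1,
                "tp": None,
                "purity_minus_kmeans": None,
                "loss": loss,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["difficulty"] = level
    frame.attrs["dist_thresh"] = dist_thresh
    frame.attrs["summary"] = ensemble_summary(ensemble)
    return frame


def plot_purity_comparison(tables: Mapping[str, pd.DataFrame], ax=None):
    """Bar chart of per-target purity difference against the k-means baseline.

    ``tables`` maps a target label to its ``compare_methods`` output. Returns
    the matplotlib axes (figure fidelity is not a goal; this is a quick-look
    helper).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.2 * len(tables), 4))
    methods = ["Community-Select", "Basins-Select", "ML-Select"]
    width = 0.8 / len(methods)
    targets = list(tables)
    for k, method in enumerate(methods):
        diffs = []
        for t in targets:
            idx = tables[t].set_index("method")
            diffs.append(
                idx.loc[method, "purity_minus_kmeans"]
                if method in idx.index
                else np.nan
            )
        ax.bar(np.arange(len(targets)) + k * width, diffs, width, label=method)
    ax.set_xticks(np.arange(len(targets)) + 0.4 - width / 2)
    ax.set_xticklabels(targets, rotation=45, ha="right")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_ylabel("purity - KMeans-Select purity")
    ax.legend(fontsize=8)
    return ax
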