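"""Supervised basin selection: difficulty prediction, purity regression, purification.

The pipeline mirrors how a practitioner would use the basin machinery when
the native structure is unknown. First, landscape-level summary features
(extremes of basin size, focal energy and persistence, plus a histogram of
basin-subgraph component counts) feed a gradient-boosted classifier that
predicts the difficulty level (easy / medium / hard) of a decoy set. The
predicted level selects a matching pair of models trained on decoy sets of
the same difficulty. Phase 1 ranks basins by purity predicted from Pareto
rank/count and component-count features and keeps the top n. Phase 2
purifies those basins with a per-decoy RMSD regressor over knowledge-based
potential features, removing decoys whose predicted RMSD exceeds the
near-native threshold (optionally relaxed by tau), and returns the top l
basins re-ranked by post-purification predicted purity.

All learners are XGBoost ensembles with fixed, seeded hyperparameters
(100 trees, depth 3, learning rate 0.1, no subsampling) so runs are
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .basin_decomposition import Basin, decompose
from .landscape_graph import NNGraph, build_nn_graph
from .pareto_features import pareto_annotate
from .structures_io import Decoy, DecoyEnsemble, DistanceStore, pairwise_distances

__all__ = [
    "DatasetFeatures",
    "DifficultyModel",
    "PurityModel",
    "RmsdModel",
    "ModelLibrary",
    "PurifiedBasin",
    "MLSelectResult",
    "dataset_features",
    "basin_feature_rows",
    "train_difficulty_classifier",
    "leave_one_out_difficulty",
    "train_purity_regressor",
    "phase1_select",
    "train_rmsd_regressor",
    "purify_basins",
    "landscape_decomposition",
    "train_model_library",
    "ml_select_pipeline",
]

DIFFICULTY_LEVELS = ("easy", "medium", "hard")
CC_BIN_LABELS = ("1", "2", "3-5", "6-10", ">10")

# fixed for reproducibility; min_child_weight=0 lets trees split the very
# small dataset-level training sets (a handful of decoy sets, one row each)
_XGB_PARAMS = dict(
    n_estimators=100,
    max_depth=3,
    learning_rate=0.1,
    subsample=1.0,
    min_child_weight=0,
    n_jobs=1,
    tree_method="hist",
)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


@dataclass
class DatasetFeatures:
    """Landscape-level summary of a decomposed decoy set."""

    min_basin_size: int
    max_basin_size: int
    min_focal_energy: float
    max_focal_energy: float
    min_persistence: float
    max_persistence: float
    cc_histogram: np.ndarray  # frequencies over bins {1, 2, 3-5, 6-10, >10}

    FEATURE_NAMES = (
        "min_basin_size",
        "max_basin_size",
        "min_focal_energy",
        "max_focal_energy",
        "min_persistence",
        "max_persistence",
        "cc_1",
        "cc_2",
        "cc_3_5",
        "cc_6_10",
        "cc_gt10",
    )

    def vector(self) -> np.ndarray:
        return np.concatenate(
            [
                [
                    self.min_basin_size,
                    self.max_basin_size,
                    self.min_focal_energy,
                    self.max_focal_energy,
                    self.min_persistence,
                    self.max_persistence,
                ],
                self.cc_histogram,
            ]
        ).astype(float)


def _cc_bin(count: int) -> int:
    if count <= 1:
        return 0
    if count == 2:
        return 1
    if count <= 5:
        return 2
    if count <= 10:
        return 3
    return 4


def dataset_features(
    basins: Sequence[Basin], distances: DistanceStore | None = None
) -> DatasetFeatures:
    """Aggregate basin statistics into the difficulty-classifier feature vector."""
    if not basins:
        raise ValueError("need at least one basin")
    if any(b.persistence is None for b in basins):
        raise ValueError("basins must carry persistence (run decompose first)")
    if any(b.n_components is None for b in basins):
        if distances is None:
            raise ValueError(
                "basins lack component counts and no distances were given"
            )
        from .basin_decomposition import basin_subgraph_components

        for b in basins:
            if b.n_components is None:
                b.n_components = basin_subgraph_components(b, distances)
    sizes = [b.size for b in basins]
    focal = [b.focal_energy for b in basins]
    pers = [b.persistence for b in basins]
    hist = np.zeros(5)
    for b in basins:
        hist[_cc_bin(b.n_components)] += 1
    return DatasetFeatures(
        min_basin_size=int(min(sizes)),
        max_basin_size=int(max(sizes)),
        min_focal_energy=float(min(focal)),
        max_focal_energy=float(max(focal)),
        min_persistence=float(min(pers)),
        max_persistence=float(max(pers)),
        cc_histogram=hist,
    )


BASIN_FEATURE_NAMES = ("pareto_rank", "pareto_count", "n_components")


def basin_feature_rows(basins: Sequence[Basin], normalize: bool = True) -> np.ndarray:
    """(n_basins, 3) Phase-1 feature matrix: Pareto rank, count, components.

    With ``normalize=True`` (the default used throughout the pipeline) the
    rank and count are divided by n_basins - 1, turning them into the
    fraction of other basins dominating / dominated by each basin. Raw
    dominance counts scale with how many basins an ensemble happens to
    fragment into, so the fractions are what transfer between decoy sets of
    different sizes.
    """
    rows = []
    for b in basins:
        if b.pareto_rank is None or b.pareto_count is None:
            raise ValueError("basins lack Pareto features (run pareto_annotate)")
        if b.n_components is None:
            raise ValueError("basins lack component counts")
        rows.append([b.pareto_rank, b.pareto_count, b.n_components])
    out = np.asarray(rows, dtype=float)
    if normalize and len(out):
        denom = max(len(basins) - 1, 1)
        out[:, 0] /= denom
        out[:, 1] /= denom
    return out


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def _save_booster(estimator, path) -> None:
    import xgboost as xgb

    bst = estimator if isinstance(estimator, xgb.Booster) else estimator.get_booster()
    bst.save_model(str(path))


def _load_booster(path):
    import xgboost as xgb

    bst = xgb.Booster()
    bst.load_model(str(path))
    return bst


def _regress(booster, X: np.ndarray) -> np.ndarray:
    """Regression predictions from a fitted sklearn estimator or raw Booster."""
    import xgboost as xgb

    if isinstance(booster, xgb.Booster):
        return booster.inplace_predict(X)
    return booster.predict(X)


@dataclass
class DifficultyModel:
    """Boosted-tree classifier over DatasetFeatures vectors."""

    booster: object
    classes: tuple[str, ...]
    mode: str
    seed: int

    def predict(self, features: DatasetFeatures) -> str:
        import xgboost as xgb

        x = features.vector()[None, :]
        if isinstance(self.booster, xgb.Booster):
            p = self.booster.inplace_predict(x)
            idx = int(np.argmax(p[0])) if p.ndim == 2 else int(p[0] > 0.5)
        else:
            idx = int(self.booster.predict(x)[0])
        return self.classes[idx]


@dataclass
class PurityModel:
    """Boosted-tree regressor from basin features to purity in [0, 1]."""

    booster: object
    seed: int

    def predict(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return np.clip(_regress(self.booster, rows), 0.0, 1.0)


@dataclass
class RmsdModel:
    """Boosted-tree regressor from potential features to per-decoy RMSD (A)."""

    booster: object
    n_features: int
    seed: int

    def predict(self, potentials: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(potentials, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} potential features, got {X.shape[1]}"
            )
        return np.maximum(_regress(self.booster, X), 0.0)


def _collapse_binary(label: str) -> str:
    # the binary setting drops the medium class into hard
    return "hard" if label == "medium" else label


def train_difficulty_classifier(
    labeled: Sequence[tuple[DatasetFeatures, str]],
    mode: str = "multiclass",
    seed: int = 0,
) -> DifficultyModel:
    """Fit the dataset-difficulty classifier from labeled feature vectors."""
    from xgboost import XGBClassifier

    if mode not in ("binary", "multiclass"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = [
        _collapse_binary(lab) if mode == "binary" else lab for _, lab in labeled
    ]
    for lab in labels:
        if lab not in DIFFICULTY_LEVELS:
            raise ValueError(f"unknown difficulty label {lab!r}")
    classes = tuple(sorted(set(labels)))
    expected = ("easy", "hard") if mode == "binary" else DIFFICULTY_LEVELS
    missing = set(expected) - set(classes)
    if missing:
        raise ValueError(f"training set lacks class(es): {sorted(missing)}")
    X = np.stack([f.vector() for f, _ in labeled])
    y = np.array([classes.index(lab) for lab in labels])
    clf = XGBClassifier(random_state=seed, **_XGB_PARAMS)
    clf.fit(X, y)
    return DifficultyModel(booster=clf, classes=classes, mode=mode, seed=seed)


def leave_one_out_difficulty(
    labeled: Sequence[tuple[DatasetFeatures, str]],
    mode: str = "multiclass",
    seed: int = 0,
) -> list[str]:
    """Leave-target-out protocol: each decoy set predicted by a model trained
    on all the others. Returns the held-out predictions in input order."""
    preds = []
    for i in range(len(labeled)):
        train = [pair for j, pair in enumerate(labeled) if j != i]
        model = train_difficulty_classifier(train, mode=mode, seed=seed)
        preds.append(model.predict(labeled[i][0]))
    return preds


def train_purity_regressor(
    rows: Sequence[tuple[np.ndarray, float]], seed: int = 0
) -> PurityModel:
    """Fit the Phase-1 purity regressor from (basin features, purity) pairs."""
    from xgboost import XGBRegressor

    if len(rows) < 2:
        raise ValueError("need at least 2 training rows")
    X = np.stack([np.asarray(r, dtype=float) for r, _ in rows])
    y = np.array([p for _, p in rows], dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("purities must lie in [0, 1]")
    reg = XGBRegressor(random_state=seed, **_XGB_PARAMS)
    reg.fit(X, y)
    return PurityModel(booster=reg, seed=seed)


def phase1_select(
    basins: Sequence[Basin], model: PurityModel, n: int = 5
) -> list[Basin]:
    """Top-n basins by predicted purity (descending; ties by size, then id).

    Predictions are attached to the basins as ``predicted_purity``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    preds = model.predict(basin_feature_rows(basins))
    for b, p in zip(basins, preds):
        b.predicted_purity = float(p)
    ranked = sorted(
        basins, key=lambda b: (-b.predicted_purity, -b.size, b.focal_id)
    )
    return ranked[: min(n, len(ranked))]


def train_rmsd_regressor(decoys: Sequence[Decoy], seed: int = 0) -> RmsdModel:
    """Fit the Phase-2 per-decoy RMSD regressor on potential features."""
    from xgboost import XGBRegressor

    if not decoys:
        raise ValueError("no training decoys")
    lens = {len(d.potentials) for d in decoys if d.potentials is not None}
    if any(d.potentials is None for d in decoys) or len(lens) != 1:
        raise ValueError("decoys must all carry potentials of one length")
    if any(d.true_rmsd is None for d in decoys):
        raise ValueError("training decoys must carry true_rmsd")
    X = np.stack([d.potentials for d in decoys])
    y = np.array([d.true_rmsd for d in decoys], dtype=float)
    reg = XGBRegressor(random_state=seed, **_XGB_PARAMS)
    reg.fit(X, y)
    return RmsdModel(booster=reg, n_features=X.shape[1], seed=seed)


# ---------------------------------------------------------------------------
# purification
# ---------------------------------------------------------------------------


@dataclass
class PurifiedBasin:
    """A basin after Phase-2 purification: kept members and their predictions."""

    basin: Basin
    kept_ids: list[str]
    predicted_rmsd: dict[str, float]
    predicted_purity: float
    focal_id: str

    @property
    def size(self) -> int:
        return len(self.kept_ids)


def purify_basins(
    top_basins: Sequence[Basin],
    model: RmsdModel,
    ensemble: DecoyEnsemble,
    dist_thresh: float,
    tau_frac: float = 0.0,
    l: int = 1,
) -> list[PurifiedBasin]:
    """Remove decoys predicted beyond the near-native threshold, keep top l.

    A decoy is removed when its predicted RMSD exceeds
    dist_thresh * (1 + tau_frac); the tau relaxation guards against the
    purification discarding true near-natives (a negative tau_frac tightens
    instead). Emptied basins are dropped. Survivors are re-ranked by
    post-purification predicted purity -- the fraction of kept decoys whose
    predicted RMSD is under dist_thresh -- with ties by size, then focal id.
    If the focal decoy is removed, the kept minimum-energy member becomes the
    focal.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    cutoff = dist_thresh * (1.0 + tau_frac)
    energies = {d.id: d.energy for d in ensemble.decoys}
    purified = []
    for basin in top_basins:
        pots = np.stack([ensemble[i].potentials for i in basin.members])
        pred = model.predict(pots)
        kept = [i for i, p in zip(basin.members, pred) if p <= cutoff]
        if not kept:
            continue
        pred_map = dict(zip(basin.members, map(float, pred)))
        n_good = sum(1 for i in kept if pred_map[i] < dist_thresh)
        focal = (
            basin.focal_id
            if basin.focal_id in kept
            else min(kept, key=lambda i: (energies[i], i))
        )
        purified.append(
            PurifiedBasin(
                basin=basin,
                kept_ids=sorted(kept),
                predicted_rmsd=pred_map,
                predicted_purity=n_good / len(kept),
                focal_id=focal,
            )
        )
    if not purified:
        raise ValueError(
            "purification emptied every basin; consider a larger tau_frac"
        )
    purified.sort(
        key=lambda pb: (-pb.predicted_purity, -pb.size, pb.basin.focal_id)
    )
    return purified[: min(l, len(purified))]


# ---------------------------------------------------------------------------
# model library and end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class LevelModels:
    purity_model: PurityModel
    rmsd_model: RmsdModel
    dist_thresh: float


@dataclass
class ModelLibrary:
    """Difficulty classifier plus per-level Phase-1/Phase-2 models."""

    difficulty_model: DifficultyModel
    levels: dict[str, LevelModels]
    seed: int
    n_potentials: int

    def for_level(self, level: str) -> LevelModels:
        if level not in self.levels:
            raise KeyError(
                f"no models for difficulty level {level!r}; "
                f"available: {sorted(self.levels)}"
            )
        return self.levels[level]

    def save(self, out_dir: str | Path) -> Path:
        """Persist the library: XGBoost JSON model files + a manifest with
        the feature-order contract."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "seed": self.seed,
            "n_potentials": self.n_potentials,
            "difficulty": {
                "file": "difficulty.json",
                "classes": list(self.difficulty_model.classes),
                "mode": self.difficulty_model.mode,
                "features": list(DatasetFeatures.FEATURE_NAMES),
            },
            "levels": {},
        }
        _save_booster(self.difficulty_model.booster, out_dir / "difficulty.json")
        for level, lm in self.levels.items():
            _save_booster(lm.purity_model.booster, out_dir / f"purity_{level}.json")
            _save_booster(lm.rmsd_model.booster, out_dir / f"rmsd_{level}.json")
            manifest["levels"][level] = {
                "purity_file": f"purity_{level}.json",
                "rmsd_file": f"rmsd_{level}.json",
                "dist_thresh": lm.dist_thresh,
                "purity_features": list(BASIN_FEATURE_NAMES),
                "n_potentials": lm.rmsd_model.n_features,
            }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path

    @classmethod
    def load(cls, in_dir: str | Path) -> "ModelLibrary":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        seed = manifest["seed"]
        difficulty = DifficultyModel(
            booster=_load_booster(in_dir / manifest["difficulty"]["file"]),
            classes=tuple(manifest["difficulty"]["classes"]),
            mode=manifest["difficulty"]["mode"],
            seed=seed,
        )
        levels = {}
        for level, entry in manifest["levels"].items():
            levels[level] = LevelModels(
                purity_model=PurityModel(
                    booster=_load_booster(in_dir / entry["purity_file"]), seed=seed
                ),
                rmsd_model=RmsdModel(
                    booster=_load_booster(in_dir / entry["rmsd_file"]),
                    n_features=entry["n_potentials"],
                    seed=seed,
                ),
                dist_thresh=entry["dist_thresh"],
            )
        return cls(
            difficulty_model=difficulty,
            levels=levels,
            seed=seed,
            n_potentials=manifest["n_potentials"],
        )


def landscape_decomposition(
    ensemble: DecoyEnsemble,
    epsilon0: float = 1.0,
    max_iter: int = 10,
    eps_step: float = 0.5,
    max_nn: int = 100,
    cache_dir: str | Path | None = None,
    distances: DistanceStore | None = None,
) -> tuple[DistanceStore, NNGraph, list[Basin]]:
    """Distances, nn-graph and fully annotated basins for one ensemble."""
    if distances is None:
        distances = pairwise_distances(ensemble, cache_dir=cache_dir)
    graph = build_nn_graph(
        distances,
        epsilon0=epsilon0,
        max_iter=max_iter,
        eps_step=eps_step,
        max_nn=max_nn,
    )
    basins = decompose(graph, ensemble.energies(), distances=distances)
    pareto_annotate(basins)
    return distances, graph, basins


def train_model_library(
    train_sets: Sequence[tuple[DecoyEnsemble, list[Basin]]],
    seed: int = 0,
    mode: str = "multiclass",
) -> ModelLibrary:
    """Build the difficulty-conditional model library from labeled decoy sets.

    Each training entry is an ensemble with native structure plus its
    decomposed, Pareto-annotated basins. Difficulty labels, per-target
    near-native thresholds, and basin purities are derived from the native
    via the standard categorization rules; one purity regressor and one RMSD
    regressor are fitted per difficulty level present.
    """
    from .evaluation import categorize_difficulty, label_near_natives

    labeled_features: list[tuple[DatasetFeatures, str]] = []
    per_level_rows: dict[str, list[tuple[np.ndarray, float]]] = {}
    per_level_decoys: dict[str, list[Decoy]] = {}
    per_level_thresh: dict[str, list[float]] = {}

    for ensemble, basins in train_sets:
        rmsds = ensemble.true_rmsds()
        level, dist_thresh = categorize_difficulty(
            ensemble.min_dist,
            lambda t, r=rmsds: int(np.sum(r < t)),
        )
        feats = dataset_features(basins)
        labeled_features.append((feats, level))
        g = label_near_natives(ensemble, dist_thresh)
        X = basin_feature_rows(basins)
        for b, x in zip(basins, X):
            purity = float(np.mean([g[i] for i in b.members]))
            per_level_rows.setdefault(level, []).append((x, purity))
        per_level_decoys.setdefault(level, []).extend(ensemble.decoys)
        per_level_thresh.setdefault(level, []).append(dist_thresh)

    difficulty_model = train_difficulty_classifier(
        labeled_features, mode=mode, seed=seed
    )
    levels = {}
    for level, rows in per_level_rows.items():
        key = _collapse_binary(level) if mode == "binary" else level
        levels.setdefault(key, {"rows": [], "decoys": [], "thresh": []})
        levels[key]["rows"].extend(rows)
        levels[key]["decoys"].extend(per_level_decoys[level])
        levels[key]["thresh"].extend(per_level_thresh[level])
    built = {}
    n_pot = None
    for level, parts in levels.items():
        rmsd_model = train_rmsd_regressor(parts["decoys"], seed=seed)
        n_pot = rmsd_model.n_features
        built[level] = LevelModels(
            purity_model=train_purity_regressor(parts["rows"], seed=seed),
            rmsd_model=rmsd_model,
            dist_thresh=float(np.median(parts["thresh"])),
        )
    return ModelLibrary(
        difficulty_model=difficulty_model,
        levels=built,
        seed=seed,
        n_potentials=n_pot or 0,
    )


@dataclass
class MLSelectResult:
    """End-to-end pipeline output: predicted level and the purified basins."""

    level: str
    dist_thresh: float
    phase1_basins: list[Basin]
    selected: list[PurifiedBasin]
    basins: list[Basin]
    graph: NNGraph
    tau_frac_used: float = 0.0
    purified: bool = True

    @property
    def top(self) -> PurifiedBasin:
        return self.selected[0]


# threshold relaxations tried, in order, when purification empties every basin
TAU_MENU = (0.10, 0.20, 0.25)


def _unpurified(
    top_n: Sequence[Basin],
    model: RmsdModel,
    ensemble: DecoyEnsemble,
    dist_thresh: float,
    l: int,
) -> list[PurifiedBasin]:
    """Phase-1 ranking passed through untouched (purification abandoned)."""
    energies = {d.id: d.energy for d in ensemble.decoys}
    out = []
    for basin in top_n[: min(l, len(top_n))]:
        pred = model.predict(
            np.stack([ensemble[i].potentials for i in basin.members])
        )
        pred_map = dict(zip(basin.members, map(float, pred)))
        n_good = sum(1 for p in pred_map.values() if p < dist_thresh)
        out.append(
            PurifiedBasin(
                basin=basin,
                kept_ids=list(basin.members),
                predicted_rmsd=pred_map,
                predicted_purity=n_good / basin.size,
                focal_id=basin.focal_id,
            )
        )
    return out


def ml_select_pipeline(
    ensemble: DecoyEnsemble,
    library: ModelLibrary,
    n: int = 5,
    l: int = 1,
    tau_frac: float = 0.0,
    seed: int = 0,
    precomputed: tuple[DistanceStore, NNGraph, list[Basin]] | None = None,
    cache_dir: str | Path | None = None,
) -> MLSelectResult:
    """Decompose, predict difficulty, rank basins by predicted purity, purify.

    Deterministic given the fitted library and the inputs; ``seed`` is kept
    for interface symmetry with the unsupervised selectors.
    """
    if precomputed is None:
        precomputed = landscape_decomposition(ensemble, cache_dir=cache_dir)
    distances, graph, basins = precomputed
    feats = dataset_features(basins, distances)
    level = library.difficulty_model.predict(feats)
    models = library.for_level(level)
    top_n = phase1_select(basins, models.purity_model, n=n)

    # purification can discard every decoy of every candidate basin (for
    # instance when the predicted difficulty's threshold does not fit the
    # data); escalate tau through the standard menu, then abandon
    # purification and let the Phase-1 ranking stand
    selected, tau_used, purified = None, tau_frac, True
    for tau in (tau_frac, *(t for t in TAU_MENU if t > tau_frac)):
        try:
            selected = purify_basins(
                top_n,
                models.rmsd_model,
                ensemble,
                dist_thresh=models.dist_thresh,
                tau_frac=tau,
                l=l,
            )
            tau_used = tau
            break
        except ValueError:
            continue
    if selected is None:
        import warnings

        warnings.warn(
            "purification emptied every candidate basin even at the largest "
            "tau; returning the unpurified Phase-1 ranking",
            stacklevel=2,
        )
        selected = _unpurified(top_n, models.rmsd_model, ensemble,
                               models.dist_thresh, l)
        purified = False

    return MLSelectResult(
        level=level,
        dist_thresh=models.dist_thresh,
        phase1_basins=top_n,
        selected=selected,
        basins=basins,
        graph=graph,
        tau_frac_used=tau_used,
        purified=purified,
    )
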