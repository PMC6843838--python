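"""Supervised pipeline: features, classifiers, regressors, purification."""

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from basinselect.basin_decomposition import Basin
from basinselect.ml_select import (
    DatasetFeatures,
    basin_feature_rows,
    dataset_features,
    leave_one_out_difficulty,
    phase1_select,
    purify_basins,
    train_difficulty_classifier,
    train_purity_regressor,
    train_rmsd_regressor,
)
from basinselect.structures_io import Decoy, DecoyEnsemble


def make_basin(focal, size, energy, persistence=1.0, n_components=1,
               pareto=(0, 0), members=None):
    members = members or [focal] + [f"{focal}m{j}" for j in range(size - 1)]
    b = Basin(
        focal_id=focal,
        members=members,
        focal_energy=float(energy),
        avg_energy=float(energy),
        persistence=persistence,
        n_components=n_components,
    )
    b.pareto_rank, b.pareto_count = pareto
    return b


def feature_cloud(rng, center, n, sd=0.5):
    """DatasetFeatures drawn around a class center vector."""
    out = []
    for _ in range(n):
        v = np.asarray(center, float) + rng.normal(0.0, sd, size=11)
        out.append(
            DatasetFeatures(
                min_basin_size=max(int(v[0]), 1),
                max_basin_size=max(int(v[1]), 1),
                min_focal_energy=v[2],
                max_focal_energy=v[3],
                min_persistence=abs(v[4]),
                max_persistence=abs(v[5]),
                cc_histogram=np.abs(v[6:11]),
            )
        )
    return out


class TestDatasetFeatures:
    def test_single_basin(self):
        b = make_basin("f", 7, -3.0, persistence=2.0, n_components=1)
        f = dataset_features([b])
        assert f.min_basin_size == f.max_basin_size == 7
        assert f.min_focal_energy == f.max_focal_energy == -3.0
        assert f.min_persistence == f.max_persistence == 2.0
        assert f.cc_histogram.tolist() == [1, 0, 0, 0, 0]

    def test_component_binning(self):
        basins = [
            make_basin("a", 3, 0.0, n_components=2),
            make_basin("b", 3, 0.0, n_components=4),
        ]
        assert dataset_features(basins).cc_histogram.tolist() == [0, 1, 1, 0, 0]

    def test_matches_brute_aggregation(self, rng):
        for _ in range(10):
            basins = [
                make_basin(
                    f"f{i}",
                    int(rng.integers(1, 30)),
                    float(rng.normal()),
                    persistence=float(rng.uniform(0, 5)),
                    n_components=int(rng.integers(1, 15)),
                )
                for i in range(int(rng.integers(1, 12)))
            ]
            f = dataset_features(basins)
            assert f.min_basin_size == min(b.size for b in basins)
            assert f.max_focal_energy == max(b.focal_energy for b in basins)
            assert f.cc_histogram.sum() == len(basins)
            assert f.min_persistence <= f.max_persistence


class TestDifficultyClassifier:
    def test_memorizes_separable_pair(self, rng):
        labeled = list(zip(feature_cloud(rng, np.zeros(11), 1), ["easy"])) + list(
            zip(feature_cloud(rng, np.full(11, 30.0), 1), ["hard"])
        )
        model = train_difficulty_classifier(labeled, mode="binary", seed=0)
        assert [model.predict(f) for f, _ in labeled] == ["easy", "hard"]

    def test_binary_loo_accuracy_on_separated_classes(self, rng):
        easy = feature_cloud(rng, np.zeros(11), 15, sd=1.0)
        hard = feature_cloud(rng, np.full(11, 8.0), 15, sd=1.0)
        labeled = [(f, "easy") for f in easy] + [(f, "hard") for f in hard]
        preds = leave_one_out_difficulty(labeled, mode="binary", seed=0)
        truth = [lab for _, lab in labeled]
        acc = np.mean([p == t for p, t in zip(preds, truth)])
        assert acc >= 0.8

    def test_multiclass_confusion_concentrates_on_medium(self, rng):
        # medium straddles both neighbors: half its sets resemble easy ones,
        # half resemble hard ones, while easy and hard stay well separated
        easy = feature_cloud(rng, np.zeros(11), 12, sd=0.8)
        medium = feature_cloud(rng, np.full(11, 0.3), 6, sd=0.8) + feature_cloud(
            rng, np.full(11, 5.7), 6, sd=0.8
        )
        hard = feature_cloud(rng, np.full(11, 6.0), 12, sd=0.8)
        labeled = (
            [(f, "easy") for f in easy]
            + [(f, "medium") for f in medium]
            + [(f, "hard") for f in hard]
        )
        preds = leave_one_out_difficulty(labeled, mode="multiclass", seed=0)
        errors = {"easy": 0, "medium": 0, "hard": 0}
        for (f, truth), pred in zip(labeled, preds):
            if pred != truth:
                errors[truth] += 1
        assert errors["medium"] >= max(errors["easy"], errors["hard"])

    def test_missing_class_rejected(self, rng):
        labeled = [(f, "easy") for f in feature_cloud(rng, np.zeros(11), 4)]
        with pytest.raises(ValueError, match="lacks class"):
            train_difficulty_classifier(labeled, mode="binary", seed=0)


class TestPurityRegressor:
    def test_constant_target(self, rng):
        rows = [(rng.normal(size=3), 0.4) for _ in range(10)]
        model = train_purity_regressor(rows, seed=0)
        preds = model.predict(np.stack([r for r, _ in rows]))
        assert preds == pytest.approx([0.4] * 10, abs=1e-6)

    def test_monotone_in_rank_recovered(self, rng):
        # purity is a noiseless decreasing function of pareto_rank
        ranks = rng.uniform(0, 1, size=300)
        rows = [
            (np.array([r, rng.uniform(0, 1), rng.integers(1, 5)]), float(1.0 - r))
            for r in ranks
        ]
        model = train_purity_regressor(rows[:200], seed=0)
        X_test = np.stack([r for r, _ in rows[200:]])
        y_test = np.array([p for _, p in rows[200:]])
        rho = spearmanr(model.predict(X_test), y_test).statistic
        assert rho >= 0.9

    def test_predictions_clamped(self, rng):
        rows = [(np.array([0.0, 0.0, 1.0]), 1.0), (np.array([1.0, 1.0, 9.0]), 0.0)]
        model = train_purity_regressor(rows * 3, seed=0)
        wild = rng.normal(scale=50.0, size=(50, 3))
        preds = model.predict(wild)
        assert np.all(preds >= 0.0) and np.all(preds <= 1.0)

    def test_out_of_range_purity_rejected(self, rng):
        with pytest.raises(ValueError):
            train_purity_regressor(
                [(np.zeros(3), 1.2), (np.ones(3), 0.5)], seed=0
            )


class TestPhase1Select:
    def _model_with_preds(self, basins, preds):
        class Stub:
            def predict(self, rows):
                return np.asarray(preds[: len(rows)])

        from basinselect.ml_select import PurityModel

        return PurityModel(booster=Stub(), seed=0)

    def test_orders_by_prediction(self):
        basins = [
            make_basin("a", 5, 0.0), make_basin("b", 5, 0.0), make_basin("c", 5, 0.0)
        ]
        model = self._model_with_preds(basins, [0.9, 0.2, 0.5])
        top = phase1_select(basins, model, n=2)
        assert [b.focal_id for b in top] == ["a", "c"]
        assert top[0].predicted_purity == pytest.approx(0.9)

    def test_n_larger_than_basins(self):
        basins = [make_basin("a", 2, 0.0), make_basin("b", 3, 0.0)]
        model = self._model_with_preds(basins, [0.1, 0.8])
        assert len(phase1_select(basins, model, n=10)) == 2

    def test_matches_sort_oracle(self, rng):
        for _ in range(10):
            k = int(rng.integers(1, 10))
            basins = [make_basin(f"f{i}", int(rng.integers(1, 9)), 0.0) for i in range(k)]
            preds = rng.uniform(0, 1, size=k).round(3)
            model = self._model_with_preds(basins, preds)
            top = phase1_select(basins, model, n=k)
            expected = sorted(
                range(k), key=lambda i: (-preds[i], -basins[i].size, basins[i].focal_id)
            )
            assert [b.focal_id for b in top] == [basins[i].focal_id for i in expected]


def linear_potential_ensemble(rng, n=120, n_pot=6, noise=0.0):
    """Decoys whose potentials encode true RMSD linearly."""
    native = rng.normal(scale=5.0, size=(8, 3))
    a = rng.uniform(0.5, 2.0, size=n_pot)
    b = rng.normal(size=n_pot)
    decoys = []
    for i in range(n):
        r = float(rng.uniform(0.2, 10.0))
        pots = a * (r + rng.normal(0.0, noise, size=n_pot)) + b
        decoys.append(
            Decoy(
                id=f"d{i:03d}",
                coords=native + rng.normal(scale=max(r, 0.1) / 3, size=(8, 3)),
                energy=float(rng.normal()),
                potentials=pots,
                true_rmsd=r,
            )
        )
    return DecoyEnsemble(target_id="lin", decoys=decoys, native=native)


class TestRmsdRegressor:
    def test_noiseless_linear_recovery(self, rng):
        ens = linear_potential_ensemble(rng, n=400)
        model = train_rmsd_regressor(ens.decoys[:300], seed=0)
        held = ens.decoys[300:]
        preds = model.predict(np.stack([d.potentials for d in held]))
        truth = np.array([d.true_rmsd for d in held])
        assert pearsonr(preds, truth).statistic > 0.99

    def test_constant_target_constant_prediction(self, rng):
        decoys = linear_potential_ensemble(rng, n=20).decoys
        for d in decoys:
            d.true_rmsd = 2.5
        model = train_rmsd_regressor(decoys, seed=0)
        preds = model.predict(np.stack([d.potentials for d in decoys]))
        assert preds == pytest.approx([2.5] * 20, abs=1e-6)

    def test_inconsistent_feature_lengths_rejected(self, rng):
        decoys = linear_potential_ensemble(rng, n=5).decoys
        decoys[2].potentials = decoys[2].potentials[:-1]
        with pytest.raises(ValueError):
            train_rmsd_regressor(decoys, seed=0)

    def test_predictions_non_negative(self, rng):
        ens = linear_potential_ensemble(rng, n=100)
        model = train_rmsd_regressor(ens.decoys, seed=0)
        wild = rng.normal(scale=100.0, size=(30, 6))
        assert np.all(model.predict(wild) >= 0.0)


class TestPurify:
    def _setup(self, rng, pred_rmsds):
        """Ensemble + one basin whose decoys have given true RMSDs, with a
        perfectly informative regressor."""
        ens = linear_potential_ensemble(rng, n=60)
        model = train_rmsd_regressor(ens.decoys, seed=0)
        # pick decoys with true RMSD closest to the requested values
        truth = np.array([d.true_rmsd for d in ens.decoys])
        chosen = []
        for target in pred_rmsds:
            i = int(np.argmin(np.abs(truth - target)))
            while ens.decoys[i].id in chosen:
                truth[i] = np.inf
                i = int(np.argmin(np.abs(truth - target)))
            chosen.append(ens.decoys[i].id)
        focal = min(chosen, key=lambda i: ens[i].energy)
        basin = make_basin(focal, len(chosen), ens[focal].energy, members=sorted(chosen))
        return ens, model, basin

    def test_all_below_threshold_unchanged(self, rng):
        ens, model, basin = self._setup(rng, [0.5, 1.0, 1.5])
        (pb,) = purify_basins([basin], model, ens, dist_thresh=50.0, l=1)
        assert pb.kept_ids == basin.members

    def test_threshold_rule_removes_far_decoy(self, rng):
        ens, model, basin = self._setup(rng, [1.0, 2.0, 9.0])
        (pb,) = purify_basins([basin], model, ens, dist_thresh=3.0, tau_frac=0.0, l=1)
        assert pb.size == 2
        removed = set(basin.members) - set(pb.kept_ids)
        assert len(removed) == 1
        assert ens[removed.pop()].true_rmsd > 3.0

    def test_never_grows_and_focal_reassigned(self, rng):
        ens, model, basin = self._setup(rng, [1.0, 2.0, 4.0, 8.0])
        # force the focal to be a removed (far) decoy
        far = max(basin.members, key=lambda i: ens[i].true_rmsd)
        basin.focal_id = far
        basin.focal_energy = ens[far].energy
        (pb,) = purify_basins([basin], model, ens, dist_thresh=3.0, l=1)
        assert pb.size <= basin.size
        assert pb.focal_id in pb.kept_ids
        kept_energies = {i: ens[i].energy for i in pb.kept_ids}
        assert pb.focal_id == min(kept_energies, key=lambda i: (kept_energies[i], i))

    def test_all_emptied_raises_with_advice(self, rng):
        ens, model, basin = self._setup(rng, [8.0, 9.0])
        with pytest.raises(ValueError, match="tau_frac"):
            purify_basins([basin], model, ens, dist_thresh=0.1, l=1)

    def test_tau_relaxes_threshold(self, rng):
        ens, model, basin = self._setup(rng, [1.0, 3.2])
        (strict,) = purify_basins([basin], model, ens, dist_thresh=3.0, l=1)
        (relaxed,) = purify_basins(
            [basin], model, ens, dist_thresh=3.0, tau_frac=0.25, l=1
        )
        assert strict.size <= relaxed.size


class TestLibraryPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        from basinselect.ml_select import (
            LevelModels,
            ModelLibrary,
        )

        easy = feature_cloud(rng, np.zeros(11), 4)
        hard = feature_cloud(rng, np.full(11, 10.0), 4)
        labeled = [(f, "easy") for f in easy] + [(f, "hard") for f in hard]
        clf = train_difficulty_classifier(labeled, mode="binary", seed=0)
        ens = linear_potential_ensemble(rng, n=50)
        rmsd_model = train_rmsd_regressor(ens.decoys, seed=0)
        purity_model = train_purity_regressor(
            [(rng.normal(size=3), float(p)) for p in rng.uniform(0, 1, 10)], seed=0
        )
        lib = ModelLibrary(
            difficulty_model=clf,
            levels={
                "easy": LevelModels(purity_model, rmsd_model, 2.0),
                "hard": LevelModels(purity_model, rmsd_model, 4.5),
            },
            seed=0,
            n_potentials=rmsd_model.n_features,
        )
        lib.save(tmp_path)
        back = ModelLibrary.load(tmp_path)
        assert back.for_level("hard").dist_thresh == 4.5
        for f, _ in labeled:
            assert back.difficulty_model.predict(f) == clf.predict(f)
        X = np.stack([d.potentials for d in ens.decoys[:10]])
        assert np.allclose(
            back.for_level("easy").rmsd_model.predict(X), rmsd_model.predict(X)
        )
        with pytest.raises(KeyError, match="available"):
            back.for_level("medium")
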