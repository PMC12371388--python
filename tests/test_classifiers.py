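import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestCentroid

from ilclass.classifiers import (
    KNNSpec,
    KNNSpectrumClassifier,
    MLPSpec,
    MLPSpectrumClassifier,
    ModelError,
    RFSpec,
    RandomForestSpectrumClassifier,
    RepresentativeSpectrumClassifier,
    grid_search_rf,
    make_classifier,
    tune_k,
)
from ilclass.preprocess import fit_bounds


@pytest.fixture(scope="module")
def separable():
    """Thirty well-separated 8-bin spectra, ten per class, in [0, 1]."""
    rng = np.random.default_rng(7)
    X, y = [], []
    for i, label in enumerate(["BZ", "PD", "HR"]):
        block = np.zeros((10, 8))
        block[:, 2 * i : 2 * i + 2] = 0.9
        X.append(block + rng.uniform(0, 0.05, (10, 8)))
        y += [label] * 10
    return np.vstack(X), np.array(y, dtype=object)


class TestRepresentativeSpectrum:
    def test_mean_of_one_equals_the_spectrum(self):
        X = np.array([[0.1, 0.2], [0.8, 0.9], [0.4, 0.5]])
        y = np.array(["BZ", "PD", "HR"], dtype=object)
        model = RepresentativeSpectrumClassifier().fit(X, y)
        for i, c in enumerate(model.classes_):
            np.testing.assert_array_equal(model.centroids_[i], X[list(y).index(c)])

    def test_centroids_equal_brute_force_means(self, separable):
        X, y = separable
        model = RepresentativeSpectrumClassifier().fit(X, y)
        for ci, c in enumerate(model.classes_):
            rows = X[y == c]
            expected = np.array(
                [sum(rows[:, j]) / len(rows) for j in range(X.shape[1])]
            )
            np.testing.assert_allclose(model.centroids_[ci], expected, atol=1e-12)

    def test_two_class_euclidean_toy(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array(["PD", "BZ"], dtype=object)
        model = RepresentativeSpectrumClassifier().fit(X, y)
        assert model.predict([[0.1, 0.0]])[0] == "PD"

    def test_agrees_with_sklearn_nearest_centroid(self, separable):
        X, y = separable
        ours = RepresentativeSpectrumClassifier().fit(X, y)
        ref = NearestCentroid(metric="euclidean").fit(X, y.astype(str))
        rng = np.random.default_rng(0)
        query = rng.uniform(0, 1, (50, X.shape[1]))
        np.testing.assert_array_equal(
            ours.predict(query).astype(str), ref.predict(query)
        )

    def test_distance_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (12, 5))
        y = np.array(["BZ", "PD", "HR"] * 4, dtype=object)
        model = RepresentativeSpectrumClassifier().fit(X, y)
        query = rng.uniform(0, 1, (20, 5))
        for q in query:
            dists = {
                c: np.sqrt(sum((q - model.centroids_[i]) ** 2))
                for i, c in enumerate(model.classes_)
            }
            assert model.predict([q])[0] == min(sorted(dists), key=dists.get)

    def test_tie_resolves_lexicographically(self):
        X = np.array([[0.0], [1.0]])
        y = np.array(["PD", "BZ"], dtype=object)
        model = RepresentativeSpectrumClassifier().fit(X, y)
        assert model.predict([[0.5]])[0] == "BZ"

    def test_training_order_invariance(self, separable):
        X, y = separable
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(y))
        a = RepresentativeSpectrumClassifier().fit(X, y)
        b = RepresentativeSpectrumClassifier().fit(X[perm], y[perm])
        query = rng.uniform(0, 1, (30, X.shape[1]))
        np.testing.assert_array_equal(a.predict(query), b.predict(query))


class TestKNN:
    def test_k1_resubstitution_is_perfect(self, separable):
        X, y = separable
        model = KNNSpectrumClassifier(k=1).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_zero_distance_neighbor_wins(self, separable):
        X, y = separable
        model = KNNSpectrumClassifier(k=1).fit(X, y)
        assert model.predict([X[15]])[0] == y[15]

    def test_majority_vote(self):
        X = np.array([[0.0], [0.1], [0.2], [1.0]])
        y = np.array(["BZ", "BZ", "PD", "PD"], dtype=object)
        model = KNNSpectrumClassifier(k=3).fit(X, y)
        assert model.predict([[0.05]])[0] == "BZ"

    def test_vote_tie_broken_by_nearest_neighbor(self):
        # k=2: one vote each; PD neighbor is strictly nearer
        X = np.array([[0.0], [0.3]])
        y = np.array(["PD", "BZ"], dtype=object)
        model = KNNSpectrumClassifier(k=2).fit(X, y)
        assert model.predict([[0.1]])[0] == "PD"

    def test_training_order_invariance(self, separable):
        X, y = separable
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(y))
        a = KNNSpectrumClassifier(k=3).fit(X, y)
        b = KNNSpectrumClassifier(k=3).fit(X[perm], y[perm])
        query = rng.uniform(0, 1, (30, X.shape[1]))
        np.testing.assert_array_equal(a.predict(query), b.predict(query))

    def test_infeasible_k_rejected(self, separable):
        X, y = separable
        with pytest.raises(ModelError):
            KNNSpectrumClassifier(k=31).fit(X, y)


class TestRandomForest:
    def test_seeded_runs_are_reproducible(self, separable):
        X, y = separable
        spec = RFSpec(n_estimators=50)
        a = RandomForestSpectrumClassifier(spec=spec, seed=3).fit(X, y)
        b = RandomForestSpectrumClassifier(spec=spec, seed=3).fit(X, y)
        query = np.random.default_rng(1).uniform(0, 1, (20, X.shape[1]))
        np.testing.assert_array_equal(a.predict(query), b.predict(query))
        np.testing.assert_array_equal(a.predict_proba(query), b.predict_proba(query))

    def test_probability_rows_are_distributions(self, separable):
        X, y = separable
        model = RandomForestSpectrumClassifier(spec=RFSpec(n_estimators=50)).fit(X, y)
        proba = model.predict_proba(X)
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)


class TestMLP:
    def test_requires_normalized_input(self, separable):
        X, y = separable
        with pytest.raises(ModelError, match="normalized"):
            MLPSpectrumClassifier(MLPSpec(hidden_sizes=(8, 8, 8))).fit(X * 1e6, y)

    def test_reaches_full_training_accuracy_on_separable_data(self, separable):
        X, y = separable
        spec = MLPSpec(
            hidden_sizes=(32, 16, 8), learning_rate=1e-2, epochs=500,
            early_stopping=False, seed=0,
        )
        model = MLPSpectrumClassifier(spec).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_softmax_rows_sum_to_one(self, separable):
        X, y = separable
        spec = MLPSpec(hidden_sizes=(16, 8, 8), learning_rate=1e-2, epochs=50,
                       early_stopping=False, seed=0)
        model = MLPSpectrumClassifier(spec).fit(X, y)
        proba = model.predict_proba(X)
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_runs_are_reproducible(self, separable):
        X, y = separable
        spec = MLPSpec(hidden_sizes=(16, 8, 8), learning_rate=1e-2, epochs=50,
                       early_stopping=False, seed=5)
        a = MLPSpectrumClassifier(spec).fit(X, y)
        b = MLPSpectrumClassifier(spec).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_exactly_three_hidden_layers_enforced(self):
        with pytest.raises(ModelError):
            MLPSpec(hidden_sizes=(8, 8))


class TestTuning:
    def test_single_candidate_k(self, separable):
        X, y = separable
        assert tune_k(X, y, candidate_ks=[3], iterations=2).k == 3

    def test_default_k_is_three(self):
        assert KNNSpec().k == 3

    def test_recovers_cv_argmax(self, separable):
        """tune_k agrees with an independently coded CV sweep."""
        X, y = separable
        candidates = [1, 3, 5]
        chosen = tune_k(X, y, candidate_ks=candidates, folds=3, iterations=3, seed=1)

        from sklearn.metrics import f1_score

        scores = {}
        for k in candidates:
            per = []
            for it in range(3):
                skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=1 + it)
                for tr, va in skf.split(X, y):
                    m = KNNSpectrumClassifier(k=k).fit(X[tr], y[tr])
                    per.append(
                        f1_score(
                            y[va].astype(str),
                            m.predict(X[va]).astype(str),
                            average="macro",
                        )
                    )
            scores[k] = np.mean(per)
        best = min(
            (k for k in candidates if scores[k] == max(scores.values()))
        )
        assert chosen.k == best

    def test_single_point_grid_returned(self, separable):
        X, y = separable
        grid = {"n_estimators": [20], "max_features": ["sqrt"]}
        spec = grid_search_rf(X, y, grid=grid, iterations=1)
        assert spec.n_estimators == 20 and spec.max_features == "sqrt"

    def test_default_grid_spans(self):
        from ilclass.classifiers import RF_DEFAULT_GRID

        assert RF_DEFAULT_GRID["n_estimators"] == list(range(200, 1801, 200))
        assert set(RF_DEFAULT_GRID["max_features"]) == {"sqrt", "log2"}
        assert RF_DEFAULT_GRID["min_samples_split"] == [2, 5, 10]
        assert RF_DEFAULT_GRID["min_samples_leaf"] == [1, 2, 4]
        assert None in RF_DEFAULT_GRID["max_depth"]

    def test_grid_search_matches_exhaustive_recompute(self, separable):
        """Reduced-grid search equals an argmax over a recomputed CV table."""
        X, y = separable
        grid = {"n_estimators": [5, 20], "min_samples_leaf": [1, 4]}
        chosen = grid_search_rf(X, y, grid=grid, folds=3, iterations=2, seed=2)

        from sklearn.metrics import f1_score

        table = {}
        for n_est in grid["n_estimators"]:
            for leaf in grid["min_samples_leaf"]:
                per = []
                for it in range(2):
                    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=2 + it)
                    for tr, va in skf.split(X, y):
                        m = RandomForestSpectrumClassifier(
                            spec=RFSpec(n_estimators=n_est, min_samples_leaf=leaf),
                            seed=2,
                        ).fit(X[tr], y[tr])
                        per.append(
                            f1_score(
                                y[va].astype(str),
                                m.predict(X[va]).astype(str),
                                average="macro",
                            )
                        )
                table[(n_est, leaf)] = np.mean(per)
        best_score = max(table.values())
        ties = [key for key, v in table.items() if v == best_score]
        best = min(ties)  # fewer trees first; leaf count does not rank
        assert (chosen.n_estimators, chosen.min_samples_leaf) == best


class TestFactory:
    @pytest.mark.parametrize("family", ["knn", "centroid", "rf", "mlp"])
    def test_families_constructible(self, family):
        assert make_classifier(family, seed=0) is not None

    def test_unknown_family_rejected(self):
        with pytest.raises(ModelError):
            make_classifier("svm")

    def test_rf_defaults_are_tuned_operating_point(self):
        spec = RFSpec()
        assert spec.n_estimators == 200
        assert spec.max_features == "sqrt"
        assert spec.max_depth is None
        assert spec.min_samples_split == 2
        assert spec.min_samples_leaf == 1
        assert spec.bootstrap is True
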