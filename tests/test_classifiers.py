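"""ELM / SaELM training, the linear vowel gate, and model serialization."""

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from vowelage.classifiers import (
    SaELMParams,
    SLFNModel,
    activation_fn,
    elm_fit,
    elm_predict,
    elm_predict_labels,
    fit_vowel_gate,
    hidden_output_matrix,
    load_model,
    one_hot_targets,
    predict_vowel,
    saelm_fit,
    save_model,
)
from vowelage.synth import synth_feature_clusters


class TestActivations:
    def test_sigmoid_midpoint(self):
        assert activation_fn("sigmoid", 0.0) == pytest.approx(0.5)

    def test_hardlim_boundary_convention(self):
        assert activation_fn("hardlim", -0.3) == 0.0
        assert activation_fn("hardlim", 0.0) == 1.0

    def test_sin_zero(self):
        assert activation_fn("sin", 0.0) == 0.0

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            activation_fn("relu", 1.0)


def _bare_model(W, b, activation, m=2):
    return SLFNModel(
        input_weights=W,
        biases=b,
        output_weights=np.zeros((W.shape[0], m)),
        activation=activation,
        class_labels=np.arange(m),
        scale_offset=np.zeros(W.shape[1]),
        scale_factor=np.ones(W.shape[1]),
    )


class TestHiddenOutputMatrix:
    def test_identity_activation_collapses_to_product(self, rng):
        W = rng.normal(size=(5, 3))
        X = rng.normal(size=(7, 3))
        model = _bare_model(W, np.zeros(5), "identity")
        assert np.allclose(hidden_output_matrix(X, model), X @ W.T)

    def test_sigmoid_range(self, rng):
        model = _bare_model(rng.normal(size=(4, 2)), rng.normal(size=4), "sigmoid")
        H = hidden_output_matrix(rng.normal(size=(6, 2)), model)
        assert np.all((H > 0) & (H < 1))

    def test_hardlim_is_binary(self, rng):
        model = _bare_model(rng.normal(size=(4, 2)), rng.normal(size=4), "hardlim")
        H = hidden_output_matrix(rng.normal(size=(6, 2)), model)
        assert set(np.unique(H)) <= {0.0, 1.0}

    def test_dimension_mismatch_rejected(self, rng):
        model = _bare_model(rng.normal(size=(4, 3)), np.zeros(4), "sigmoid")
        with pytest.raises(ValueError):
            hidden_output_matrix(rng.normal(size=(5, 2)), model)


def _oracle_beta(model, X, labels):
    """Independent least-squares solve via ridge-0 normal equations."""
    Xs = X * model.scale_factor + model.scale_offset
    H = hidden_output_matrix(Xs, model)
    T = one_hot_targets(labels, model.class_labels)
    return np.linalg.solve(H.T @ H, H.T @ T)


class TestELM:
    def test_beta_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            N, nh, m = rng.integers(8, 21), rng.integers(2, 11), rng.integers(2, 5)
            X = rng.normal(size=(N, 3))
            y = np.r_[np.arange(m), rng.integers(0, m, N - m)]
            model = elm_fit(X, y, int(nh), "sigmoid", seed=trial)
            assert np.allclose(
                model.output_weights, _oracle_beta(model, X, y), atol=1e-8
            )

    def test_interpolation_when_hidden_equals_samples(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.integers(0, 2, 10)
        y[:2] = [0, 1]
        model = elm_fit(X, y, n_hidden=10, activation="sigmoid", seed=3)
        Xs = X * model.scale_factor + model.scale_offset
        H = hidden_output_matrix(Xs, model)
        T = one_hot_targets(y, model.class_labels)
        assert np.linalg.norm(H @ model.output_weights - T) < 1e-6
        assert np.array_equal(elm_predict_labels(model, X), y)

    def test_xor_is_learned_exactly(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        model = elm_fit(X, y, n_hidden=4, activation="sigmoid", seed=0)
        assert np.array_equal(elm_predict_labels(model, X), y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            elm_fit(rng.normal(size=(6, 2)), np.zeros(6, dtype=int), 3)

    def test_nonfinite_features_rejected(self):
        X = np.array([[0.0, np.inf], [1.0, 2.0]])
        with pytest.raises(ValueError):
            elm_fit(X, [0, 1], 2)

    def test_seeded_fit_is_bit_reproducible(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.integers(0, 3, 15)
        y[:3] = [0, 1, 2]
        a = elm_fit(X, y, 6, seed=42)
        b = elm_fit(X, y, 6, seed=42)
        assert np.array_equal(a.input_weights, b.input_weights)
        assert np.array_equal(a.output_weights, b.output_weights)

    def test_predict_rows_permute_with_samples(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.integers(0, 2, 12)
        y[:2] = [0, 1]
        model = elm_fit(X, y, 5, seed=1)
        perm = rng.permutation(12)
        assert np.allclose(elm_predict(model, X)[perm], elm_predict(model, X[perm]))

    def test_training_sample_of_interpolating_model_scores_one_hot(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.integers(0, 2, 8)
        y[:2] = [0, 1]
        model = elm_fit(X, y, n_hidden=8, seed=5)
        score = elm_predict(model, X[3])
        expected = one_hot_targets([y[3]], model.class_labels)[0]
        assert np.allclose(score[0], expected, atol=1e-6)


def _two_cluster_problem(seed, n=100, p=4, separation=6.0):
    r = np.random.default_rng(seed)
    X = np.vstack(
        [r.normal(0, 1, size=(n // 2, p)), r.normal(separation, 1, size=(n // 2, p))]
    )
    y = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
    return X, y


def _elm_validation_rmse(X, y, n_hidden, seed, validation_fraction=0.2):
    """Fitness of a plain ELM computed the same way SaELM scores individuals."""
    idx_tr, idx_val = train_test_split(
        np.arange(len(y)),
        test_size=validation_fraction,
        stratify=y,
        random_state=seed,
    )
    model = elm_fit(X[idx_tr], y[idx_tr], n_hidden, seed=seed)
    T_val = one_hot_targets(y[idx_val], model.class_labels)
    resid = elm_predict(model, X[idx_val]) - T_val
    return float(np.sqrt(np.mean(resid**2)))


class TestSaELM:
    def test_best_fitness_is_monotone_non_increasing(self):
        X, y = _two_cluster_problem(0, n=60, separation=3.0)
        params = SaELMParams(
            population_size=8, generations=6, n_hidden=10, seed=11
        )
        model = saelm_fit(X, y, params)
        h = model.fitness_history
        assert len(h) == 7
        assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))
        assert h[-1] <= h[0]

    def test_zero_generations_returns_best_of_initial_population(self):
        X, y = _two_cluster_problem(1, n=40)
        params = SaELMParams(
            population_size=6, generations=0, n_hidden=5, seed=21
        )
        model = saelm_fit(X, y, params)
        # reconstruct the seeded initial population and score each individual
        # through an independent ELM path; the winner must match the model
        dim = params.n_hidden * (X.shape[1] + 1)
        pop = np.random.default_rng(params.seed).uniform(
            -1.0, 1.0, size=(params.population_size, dim)
        )
        idx_tr, idx_val = train_test_split(
            np.arange(len(y)),
            test_size=params.validation_fraction,
            stratify=y,
            random_state=params.seed,
        )
        offset, factor = model.scale_offset, model.scale_factor
        Xs = X * factor + offset
        T = one_hot_targets(y, model.class_labels)
        fits = []
        for vec in pop:
            W = vec[: params.n_hidden * X.shape[1]].reshape(params.n_hidden, -1)
            b = vec[params.n_hidden * X.shape[1] :]
            g = lambda z: 1.0 / (1.0 + np.exp(-z))
            H_tr = g(Xs[idx_tr] @ W.T + b)
            beta, *_ = np.linalg.lstsq(H_tr, T[idx_tr], rcond=None)
            resid = g(Xs[idx_val] @ W.T + b) @ beta - T[idx_val]
            fits.append(np.sqrt(np.mean(resid**2)))
        best = pop[int(np.argmin(fits))]
        W_best = best[: params.n_hidden * X.shape[1]].reshape(params.n_hidden, -1)
        assert np.array_equal(model.input_weights, W_best)
        assert model.fitness_history == [pytest.approx(min(fits))]

    def test_separated_clusters_trained_perfectly_and_beats_plain_elm(self):
        saelm_fitness, elm_fitness = [], []
        for seed in range(5):
            X, y = _two_cluster_problem(seed, n=100, p=4, separation=6.0)
            params = SaELMParams(
                population_size=10, generations=5, n_hidden=8, seed=seed
            )
            model = saelm_fit(X, y, params)
            assert np.array_equal(elm_predict_labels(model, X), y)
            saelm_fitness.append(model.fitness_history[-1])
            elm_fitness.append(_elm_validation_rmse(X, y, 8, seed))
        assert np.median(saelm_fitness) <= np.median(elm_fitness)

    def test_population_too_small_rejected(self):
        with pytest.raises(ValueError):
            SaELMParams(population_size=4)

    def test_seeded_fit_is_bit_reproducible(self):
        X, y = _two_cluster_problem(2, n=40)
        params = SaELMParams(population_size=6, generations=2, n_hidden=5, seed=9)
        a = saelm_fit(X, y, params)
        b = saelm_fit(X, y, params)
        assert np.array_equal(a.input_weights, b.input_weights)
        assert np.array_equal(a.output_weights, b.output_weights)


class TestVowelGate:
    def test_two_separable_clusters_and_margin_constraints(self):
        r = np.random.default_rng(0)
        X = np.vstack([r.normal(0, 0.5, (30, 3)), r.normal(5, 0.5, (30, 3))])
        labels = np.array(["a"] * 30 + ["i"] * 30)
        gate = fit_vowel_gate(X, labels)
        assert np.all(predict_vowel(gate, X) == labels)
        w, b = gate.pair_weights[0], gate.pair_biases[0]
        y_signed = np.where(labels == gate.class_labels[0], -1.0, 1.0)
        margins = y_signed * (X @ w + b)
        assert np.all(margins >= 1.0 - 1e-6)

    def test_six_separable_vowel_clusters(self):
        frame = synth_feature_clusters(
            n_classes=2, n_per_class=30, dim=8, separation=0.0, seed=4,
            streams=list("aeiouy"), stream_offset=10.0,
        )
        cols = [c for c in frame.columns if c.startswith("f0")]
        X = frame[cols].to_numpy()
        labels = frame["vowel"].to_numpy()
        gate = fit_vowel_gate(X, labels)
        acc = np.mean(predict_vowel(gate, X) == labels)
        assert acc >= 0.99

    def test_permuted_labels_score_near_chance(self):
        r = np.random.default_rng(8)
        X = r.normal(size=(600, 6))
        labels = np.repeat(list("aeiouy"), 100)
        labels = labels[r.permutation(600)]
        correct = 0
        for fold in range(3):
            test = np.arange(600) % 3 == fold
            gate = fit_vowel_gate(X[~test], labels[~test])
            correct += int(np.sum(predict_vowel(gate, X[test]) == labels[test]))
        assert abs(correct / 600 - 1 / 6) < 0.03

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_vowel_gate(rng.normal(size=(10, 2)), ["a"] * 10)

    def test_prediction_is_deterministic(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(4, 1, (20, 3))])
        labels = np.array(["o"] * 20 + ["u"] * 20)
        gate = fit_vowel_gate(X, labels)
        x = rng.normal(size=3)
        assert predict_vowel(gate, x) == predict_vowel(gate, x)

    def test_far_point_along_cluster_mean_is_routed_there(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(6, 1, (30, 4))])
        labels = np.array(["e"] * 30 + ["ə"] * 30)
        gate = fit_vowel_gate(X, labels)
        assert predict_vowel(gate, np.full(4, 20.0)) == "ə"


class TestSerialization:
    def test_round_trip_reproduces_predictions_bit_exactly(self, rng, tmp_path):
        X = rng.normal(size=(20, 5))
        y = rng.integers(0, 3, 20)
        y[:3] = [0, 1, 2]
        model = elm_fit(X, y, 7, "sin", seed=13)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert np.array_equal(elm_predict(model, X), elm_predict(loaded, X))
        assert np.array_equal(loaded.class_labels, model.class_labels)
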