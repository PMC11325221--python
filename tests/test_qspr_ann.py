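"""Spearman input selection, dataset splitting, MLP training and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from desqspr import qspr_ann as qa


def make_dataset(X, k, transform="none"):
    table = pd.DataFrame(X, columns=[f"S{i}" for i in range(1, 11)])
    table.insert(0, "label", [f"DES {i}" for i in range(len(table))])
    table["k_per_h"] = k
    return qa.QSPRDataset(table=table, transform=transform)


def linear_dataset(n=84, seed=0, noise=0.0):
    """y = 2·S1 − S2 (+ noise), the identity-network sanity target."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 10, (n, 10))
    y = 2.0 * X[:, 0] - X[:, 1] + noise * rng.normal(size=n)
    return make_dataset(X, y)


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (30, 10))
        k = np.exp(3.0 * X[:, 2])  # strictly increasing in S3 only
        rho = qa.spearman_matrix(make_dataset(X, k))
        assert rho[2] == pytest.approx(1.0)

    def test_independent_response_has_small_rho(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (100, 10))
        k = rng.permutation(np.arange(100, dtype=float) + 1.0)
        rho = qa.spearman_matrix(make_dataset(X, k))
        assert np.all(np.abs(rho) < 0.25)

    def test_matches_hand_rank_formula_on_five_rows(self):
        X = np.zeros((5, 10))
        X[:, 0] = [3.0, 1.0, 4.0, 1.5, 5.0]
        k = np.array([2.0, 1.0, 3.0, 2.5, 4.0])
        rho = qa.spearman_matrix(make_dataset(X + 1.0, k))
        # Spearman = Pearson on average ranks, computed independently
        rx, ry = rankdata(X[:, 0]), rankdata(k)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_reported_as_zero_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (20, 10))
        X[:, 4] = 7.0
        with pytest.warns(UserWarning, match="S5"):
            rho = qa.spearman_matrix(make_dataset(X, X[:, 0]))
        assert rho[4] == 0.0


class TestSelectInputs:
    def test_perfect_correlations_select_everything(self):
        assert qa.select_inputs(np.ones(10), 0.5) == tuple(range(10))

    def test_mixed_signs_pass_by_magnitude(self):
        rho = np.array([0.9, -0.9, 0.1, 0, 0, 0, 0, 0, 0, -0.45])
        assert qa.select_inputs(rho, 0.4) == (0, 1, 9)

    def test_empty_selection_raises_with_advice(self):
        with pytest.raises(ValueError, match="lower the threshold"):
            qa.select_inputs(np.full(10, 0.1), 0.5)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            qa.select_inputs(np.ones(10), bad)


class TestSplitDataset:
    def test_84_point_split_counts(self):
        part = qa.split_dataset(84, qa.SplitSpec(seed=0))
        assert len(part.calibration) == 55
        assert len(part.prediction) == 29
        assert (len(part.train), len(part.test), len(part.validation)) == (39, 8, 8)

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_blocks_disjoint_and_exhaustive(self, seed):
        n = 84
        part = qa.split_dataset(n, qa.SplitSpec(seed=seed))
        combined = np.concatenate(
            [part.train, part.test, part.validation, part.prediction]
        )
        assert sorted(combined.tolist()) == list(range(n))

    def test_same_seed_reproduces_partition(self):
        p1 = qa.split_dataset(84, qa.SplitSpec(seed=3))
        p2 = qa.split_dataset(84, qa.SplitSpec(seed=3))
        for a, b in zip((p1.train, p1.test, p1.validation, p1.prediction),
                        (p2.train, p2.test, p2.validation, p2.prediction)):
            assert np.array_equal(a, b)

    def test_block_sizes_fixed_across_resamples(self):
        sizes = {
            (len(p.train), len(p.test), len(p.validation), len(p.prediction))
            for seed in range(200)
            for p in [qa.split_dataset(84, qa.SplitSpec(seed=seed))]
        }
        assert sizes == {(39, 8, 8, 29)}

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            qa.split_dataset(9, qa.SplitSpec(seed=0))


class TestTrainMLP:
    def test_linear_limit_reaches_r2_0999(self):
        dataset = linear_dataset()
        part = qa.split_dataset(dataset.n, qa.SplitSpec(seed=0))
        arch = qa.MLPArchitecture(n_inputs=10, n_hidden=4,
                                  hidden_activation="identity",
                                  output_activation="identity")
        model = qa.train_mlp(dataset, part, arch)
        assert model.metrics["r2_train"] >= 0.999
        assert model.metrics["r2_validation"] >= 0.999

    def test_zero_epoch_training_returns_initial_network(self):
        dataset = linear_dataset()
        part = qa.split_dataset(dataset.n, qa.SplitSpec(seed=0))
        arch = qa.MLPArchitecture(n_inputs=10, n_hidden=5)
        settings = qa.TrainingSettings(max_epochs=0, seed=9)
        m1 = qa.train_mlp(dataset, part, arch, settings=settings)
        m2 = qa.train_mlp(dataset, part, arch, settings=settings)
        assert np.array_equal(m1.W1, m2.W1)
        X = dataset.descriptors()
        assert np.array_equal(qa.predict(m1, X), qa.predict(m2, X))

    def test_training_error_non_increasing_for_small_step(self):
        dataset = linear_dataset()
        part = qa.split_dataset(dataset.n, qa.SplitSpec(seed=0))
        arch = qa.MLPArchitecture(n_inputs=10, n_hidden=6,
                                  hidden_activation="tanh")
        model = qa.train_mlp(
            dataset, part, arch,
            settings=qa.TrainingSettings(learning_rate=0.005, max_epochs=400,
                                         patience=400),
        )
        history = np.array(model.history)
        assert np.all(np.diff(history) <= 1e-9)

    def test_architecture_input_mismatch_rejected(self):
        dataset = linear_dataset()
        part = qa.split_dataset(dataset.n, qa.SplitSpec(seed=0))
        arch = qa.MLPArchitecture(n_inputs=3, n_hidden=4)
        with pytest.raises(ValueError, match="match"):
            qa.train_mlp(dataset, part, arch, input_indices=(0, 1))


class TestPredict:
    @staticmethod
    def trained_linear_model():
        dataset = linear_dataset()
        part = qa.split_dataset(dataset.n, qa.SplitSpec(seed=0))
        arch = qa.MLPArchitecture(n_inputs=10, n_hidden=4,
                                  hidden_activation="identity",
                                  output_activation="identity")
        return dataset, qa.train_mlp(dataset, part, arch)

    def test_identity_network_with_known_weights_is_affine(self):
        arch = qa.MLPArchitecture(n_inputs=2, n_hidden=4,
                                  hidden_activation="identity",
                                  output_activation="identity")
        W1 = np.arange(8.0).reshape(2, 4) / 10.0
        W2 = np.ones((4, 1))
        model = qa.TrainedModel(
            architecture=arch, W1=W1, b1=np.zeros(4), W2=W2, b2=np.array([0.5]),
            x_mean=np.zeros(2), x_std=np.ones(2), y_mean=0.0, y_std=1.0,
            transform="none", scale_bounds=None, input_indices=(0, 1),
            history=[1.0],
        )
        x = np.array([[1.0, 2.0]])
        expected = (x @ W1 @ W2 + 0.5)[0, 0]
        assert qa.predict(model, x)[0] == pytest.approx(expected, rel=1e-12)

    def test_batch_equals_rowwise(self):
        dataset, model = self.trained_linear_model()
        X = dataset.descriptors()[:5]
        batch = qa.predict(model, X)
        rows = np.array([qa.predict(model, x)[0] for x in X])
        assert batch == pytest.approx(rows, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        _, model = self.trained_linear_model()
        with pytest.raises(ValueError, match="columns"):
            qa.predict(model, np.ones((1, 7)))

    def test_save_load_round_trip(self, tmp_path):
        dataset, model = self.trained_linear_model()
        path = tmp_path / "model.json"
        qa.save_model(model, path)
        back = qa.load_model(path)
        X = dataset.descriptors()
        assert qa.predict(back, X) == pytest.approx(qa.predict(model, X),
                                                    rel=1e-12)
        assert back.architecture == model.architecture


class TestRandomSearch:
    def test_single_candidate_returns_that_model(self):
        dataset = linear_dataset()
        part = qa.split_dataset(dataset.n, qa.SplitSpec(seed=0))
        model, board = qa.random_search(dataset, part, tuple(range(10)),
                                        n_candidates=1, seed=5)
        assert len(board) == 1
        assert board.loc[0, "network"] == model.architecture.name

    def test_identity_restricted_search_solves_linear_data(self):
        dataset = linear_dataset()
        part = qa.split_dataset(dataset.n, qa.SplitSpec(seed=0))
        archs = [qa.MLPArchitecture(10, h, "identity", "identity")
                 for h in (4, 7, 13)]
        model, _ = qa.random_search(dataset, part, tuple(range(10)),
                                    n_candidates=3, seed=1,
                                    architectures=archs)
        assert model.metrics["r2_validation"] >= 0.999

    def test_seeded_search_is_deterministic(self):
        dataset = linear_dataset()
        part = qa.split_dataset(dataset.n, qa.SplitSpec(seed=0))
        settings = qa.TrainingSettings(max_epochs=300)
        _, b1 = qa.random_search(dataset, part, tuple(range(10)),
                                 n_candidates=8, seed=7, settings=settings)
        _, b2 = qa.random_search(dataset, part, tuple(range(10)),
                                 n_candidates=8, seed=7, settings=settings)
        pd.testing.assert_frame_equal(b1, b2)


class TestQSPRDataset:
    def test_log10_transform_round_trip(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (12, 10))
        k = 10.0 ** rng.uniform(-3, 1, 12)
        ds = make_dataset(X, k, transform="log10")
        assert ds.inverse_transform(ds.response()) == pytest.approx(k, rel=1e-12)

    def test_log10_requires_positive_rates(self):
        X = np.ones((5, 10))
        with pytest.raises(ValueError, match="positive"):
            make_dataset(X, np.array([1.0, 0.0, 2.0, 3.0, 4.0]),
                         transform="log10")

    def test_scaled_transform_is_minmax(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (10, 10))
        k = rng.uniform(2.0, 8.0, 10)
        ds = make_dataset(X, k, transform="scaled")
        y = ds.response()
        assert y.min() == pytest.approx(0.0)
        assert y.max() == pytest.approx(1.0)
        assert ds.inverse_transform(y) == pytest.approx(k, rel=1e-12)
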