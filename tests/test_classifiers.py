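import numpy as np
import pytest

from mgp.classifiers import (
    CNNModel,
    CNNSpec,
    TrainProtocol,
    accuracy,
    build_network,
    crossval_predict,
    fit_logistic,
    score_to_class,
    spatial_sizes,
)


class TestScoreToClass:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.0, "glass"), (0.49, "glass"), (0.5, "mirror"), (0.51, "mirror"), (1.0, "mirror")],
    )
    def test_threshold(self, score, expected):
        assert score_to_class(score) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            score_to_class(1.5)


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy([0.9, 0.1], ["mirror", "glass"]) == 1.0

    def test_boundary_scores_count_as_mirror(self):
        assert accuracy([0.5, 0.5], ["glass", "glass"]) == 0.0

    def test_complement_symmetry_without_boundary(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 50)
        scores = scores[np.abs(scores - 0.5) > 1e-6]
        labels = rng.integers(0, 2, len(scores))
        assert accuracy(scores, labels) + accuracy(scores, 1 - labels) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy([0.5], ["mirror", "glass"])


class TestLogistic:
    def test_separable_data_perfect_accuracy(self):
        X = np.r_[np.linspace(0, 0.3, 20), np.linspace(0.7, 1.0, 20)][:, None]
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        model = fit_logistic(X, y)
        assert accuracy(model.predict_score(X), y) == 1.0

    def test_symmetric_midpoint_scores_half(self):
        X = np.array([[0.0], [1.0], [0.2], [0.8]])
        y = np.array([0, 1, 0, 1])
        model = fit_logistic(X, y)
        assert model.predict_score(np.array([[0.5]]))[0] == pytest.approx(0.5, abs=1e-6)

    def test_planted_coefficient_sign(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (200, 3))
        y = (X[:, 1] + 0.1 * rng.normal(size=200) > 0).astype(int)
        model = fit_logistic(X, y)
        assert model.coef_[1] > 0
        assert abs(model.coef_[1]) > abs(model.coef_[0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((5, 2)), np.ones(5, dtype=int))

    def test_dominant_weight_on_cue_feature(self, strong_cue_dataset):
        # single informative feature among noise: >80% of L2 norm on it
        _, images, labels = strong_cue_dataset
        rng = np.random.default_rng(2)
        cue = np.array([im[:32].mean() - im[32:].mean() for im in images])
        X = np.c_[cue, rng.normal(0, cue.std(), (len(cue), 3))]
        X = (X - X.mean(0)) / X.std(0)
        model = fit_logistic(X, labels)
        w = model.coef_
        assert w[0] ** 2 / (w**2).sum() > 0.8


class TestCNNArchitecture:
    def test_depth3_spatial_sizes(self):
        spec = CNNSpec(depth=3, pool_size=2)
        assert spec.pooled_blocks == (0, 1, 2)
        assert spatial_sizes(spec) == [32, 16, 8]

    def test_depth1_has_one_pooled_block(self):
        spec = CNNSpec(depth=1)
        assert spec.pooled_blocks == (0,)

    def test_pooling_only_last_three_blocks(self):
        spec = CNNSpec(depth=5)
        assert spec.pooled_blocks == (2, 3, 4)
        assert spatial_sizes(spec) == [64, 64, 32, 16, 8]

    def test_parameter_count_matches_hand_count(self):
        spec = CNNSpec(depth=1, filters_base=4, kernel_size=3, fc_units=8)
        net = build_network(spec)
        conv = 3 * 3 * 3 * 4 + 4
        bn = 2 * 4
        flat = 4 * 32 * 32  # one pool stage: 64 -> 32
        dense1 = flat * 8 + 8
        dense2 = 8 * 2 + 2
        assert net.n_params() == conv + bn + dense1 + dense2

    def test_gap_head_parameter_count(self):
        spec = CNNSpec(depth=1, filters_base=4, kernel_size=3, head="gap")
        net = build_network(spec)
        assert net.n_params() == (3 * 3 * 3 * 4 + 4) + 2 * 4 + (4 * 2 + 2)

    def test_spatial_underflow_rejected(self):
        with pytest.raises(ValueError):
            spatial_sizes(CNNSpec(depth=3, pool_size=8))

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            CNNSpec(depth=0)
        with pytest.raises(ValueError):
            CNNSpec(depth=13)


class TestCNNTraining:
    def test_planted_signal_recovery(self, strong_cue_dataset, trained_dense_model):
        _, images, labels = strong_cue_dataset
        acc = accuracy(trained_dense_model.predict_score(images), labels)
        assert acc >= 0.95

    def test_shuffled_labels_give_chance(self, strong_cue_dataset):
        _, images, labels = strong_cue_dataset
        rng = np.random.default_rng(0)
        train, test = np.arange(0, 120, 2), np.arange(1, 120, 2)  # stratified halves
        shuffled = rng.permutation(labels[train])
        model = CNNModel(CNNSpec(depth=1), seed=7, max_epochs=4)
        model.fit(images[train], shuffled)
        acc = accuracy(model.predict_score(images[test]), labels[test])
        assert 0.4 <= acc <= 0.6

    def test_deterministic_given_seed(self, strong_cue_dataset):
        _, images, labels = strong_cue_dataset
        hists = []
        for _ in range(2):
            m = CNNModel(CNNSpec(depth=1), seed=9, max_epochs=3)
            m.fit(images[:60], labels[:60])
            hists.append(m.history)
        assert hists[0] == hists[1]

    def test_early_stopping_patience(self, strong_cue_dataset):
        _, images, labels = strong_cue_dataset
        m = CNNModel(CNNSpec(depth=1), seed=9, max_epochs=30, patience=3)
        m.fit(images[:60], labels[:60])
        best = max(m.history)
        # stopped no later than 3 validations after the best one
        assert len(m.history) <= m.history.index(best) + 1 + 3

    def test_empty_training_set(self):
        m = CNNModel(CNNSpec(depth=1), seed=0)
        with pytest.raises(ValueError):
            m.fit(np.empty((0, 64, 64, 3)), np.empty(0, dtype=int))


class TestCrossval:
    def test_each_image_scored_once_per_repeat(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (30, 2))
        y = (X[:, 0] > 0).astype(int)
        protocol = TrainProtocol(n_repeats=10, master_seed=0)
        from mgp.classifiers import LogisticModel

        scores, per_repeat = crossval_predict(
            lambda s: LogisticModel(seed=s), X, y, protocol, return_per_repeat=True
        )
        assert per_repeat.shape == (10, 30)
        assert np.isfinite(per_repeat).all()
        np.testing.assert_allclose(scores, per_repeat.mean(axis=0))

    def test_constant_factory_gives_half(self):
        class Constant:
            def fit(self, X, y):
                return self

            def predict_score(self, X):
                return np.full(len(X), 0.5)

        X = np.zeros((10, 1))
        y = np.array([0, 1] * 5)
        scores = crossval_predict(lambda s: Constant(), X, y, TrainProtocol(n_repeats=3))
        np.testing.assert_allclose(scores, 0.5)

    def test_two_folds_enforced(self):
        with pytest.raises(ValueError):
            TrainProtocol(n_folds=5)

    def test_factory_failure_carries_context(self):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        X = np.zeros((10, 1))
        y = np.array([0, 1] * 5)
        with pytest.raises(RuntimeError, match="repeat 0"):
            crossval_predict(lambda s: Broken(), X, y, TrainProtocol(n_repeats=1))


@pytest.mark.slow
def test_appearance_overlap_degrades_every_classifier():
    """Pushing the class appearance distributions toward 0.5 lowers the
    held-out accuracy of all three classifier families."""
    from mgp import synthetic as syn
    from mgp.features import colorhist_features, pca_reduce, texture_features, zscore

    mixes = [
        {"mirror": ("uniform", 0.8, 1.0), "glass": ("uniform", 0.0, 0.2)},
        {"mirror": ("uniform", 0.6, 1.0), "glass": ("uniform", 0.0, 0.4)},
        {"mirror": ("uniform", 0.45, 1.0), "glass": ("uniform", 0.0, 0.55)},
    ]
    proto = TrainProtocol(n_repeats=3, master_seed=5)
    accs = {"colorhist": [], "texture": [], "cnn": []}
    from mgp.classifiers import LogisticModel

    for mix in mixes:
        specs = syn.generate_specs(80, mix, 77)
        images = syn.render_specs(specs)
        y = np.array([s.true_class for s in specs])
        ch, _ = zscore(np.stack([colorhist_features(im) for im in images]))
        accs["colorhist"].append(
            accuracy(crossval_predict(lambda s: LogisticModel(seed=s), ch, y, proto), y)
        )
        tx, _ = zscore(np.stack([texture_features(im)[0] for im in images]))
        tx_red, _ = pca_reduce(tx, 0.99)
        accs["texture"].append(
            accuracy(crossval_predict(lambda s: LogisticModel(seed=s), tx_red, y, proto), y)
        )
        accs["cnn"].append(
            accuracy(
                crossval_predict(
                    lambda s: CNNModel(CNNSpec(depth=2), seed=s, max_epochs=6),
                    images, y, proto,
                ),
                y,
            )
        )
    for name, values in accs.items():
        assert values[0] >= values[1] >= values[2], (name, values)
        assert values[0] > values[2], (name, values)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, trained_dense_model,
                                              strong_cue_dataset, tmp_path):
        _, images, _ = strong_cue_dataset
        trained_dense_model.save(tmp_path / "ckpt")
        restored = CNNModel.load(tmp_path / "ckpt")
        np.testing.assert_allclose(
            restored.predict_score(images[:10]),
            trained_dense_model.predict_score(images[:10]),
            atol=1e-7,
        )
        assert restored.spec == trained_dense_model.spec


class TestActivations:
    def test_stage_capture_shapes(self, trained_dense_model, strong_cue_dataset):
        _, images, _ = strong_cue_dataset
        acts = trained_dense_model.activations(images[:4])
        names = trained_dense_model.stage_names()
        assert names[0] == "input" and names[-1] == "output"
        assert "relu1" in acts and "fc" in acts
        assert acts["input"].shape == (4, 64 * 64 * 3)
        assert acts["output"].shape == (4, 2)
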