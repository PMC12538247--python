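import numpy as np
import pytest

from eegaffect import recnet
from eegaffect.errors import ValidationError


def separable_batch(n=120, t=16, d=4, seed=0, gap=3.0):
    """Two classes distinguished by signal amplitude: trivially separable."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    amp = np.where(y == 1, gap, 1.0)[:, None, None]
    X = amp * rng.standard_normal((n, t, d))
    return X.astype(np.float32), y


class TestModelSpecs:
    def test_proposed_stack_structure(self):
        spec = recnet.proposed_model(32, 4032, 2)
        kinds = [l.kind for l in spec.layers]
        assert kinds == ["bidirectional-recurrent", "bidirectional-recurrent",
                        "dropout", "recurrent", "dense"]
        assert [l.units for l in spec.layers] == [128, 64, None, 32, 2]
        assert spec.layers[2].rate == 0.5
        assert spec.layers[-1].activation == "softmax"

    def test_dropout_rate_configurable(self):
        spec = recnet.proposed_model(32, 100, 2, dropout_rate=0.3)
        assert spec.layers[2].rate == 0.3

    @pytest.mark.parametrize(
        "name, kinds, units",
        [
            ("bilstm128-d05-lstm64",
             ["bidirectional-recurrent", "dropout", "recurrent", "dense"],
             [128, None, 64, 2]),
            ("bilstm128-d05-bilstm64",
             ["bidirectional-recurrent", "dropout", "bidirectional-recurrent", "dense"],
             [128, None, 64, 2]),
            ("lstm128-d02", ["recurrent", "dropout", "dense"], [128, None, 2]),
        ],
    )
    def test_ablation_stacks(self, name, kinds, units):
        spec = recnet.ablation_models(name, 32, 256, 2)
        assert [l.kind for l in spec.layers] == kinds
        assert [l.units for l in spec.layers] == units

    def test_unknown_ablation_lists_valid_names(self):
        with pytest.raises(ValidationError, match="bilstm128-d05-lstm64"):
            recnet.ablation_models("foo")

    def test_spec_serialization_round_trip(self):
        spec = recnet.proposed_model(8, 64, 2)
        assert recnet.ModelSpec.from_dict(spec.to_dict()) == spec


class TestParameterCounts:
    def test_first_layer_closed_form(self):
        """Bidirectional 128-unit layer on 32 features: 2*4*128*(32+128+1)."""
        spec = recnet.proposed_model(32, 4032, 2)
        first = recnet.ModelSpec(
            layers=(spec.layers[0],
                    recnet.LayerSpec("dense", units=2, activation="softmax")),
            n_classes=2, input_feature_dim=32, sequence_length=4032)
        dense_params = 2 * 128 * 2 + 2
        assert recnet.parameter_count(first) - dense_params == 164_864

    def test_proposed_total(self):
        spec = recnet.proposed_model(32, 4032, 2)
        assert recnet.parameter_count(spec) == 164_864 + 164_352 + 20_608 + 66
        assert recnet.parameter_count(spec) == 349_890

    @pytest.mark.parametrize("name", ["proposed", *recnet.ABLATION_NAMES])
    def test_closed_form_matches_per_matrix_tally(self, name):
        """The 4h(d+h+1) formula vs summing every built weight array."""
        spec = recnet.model_spec(name, 32, 64, 2)
        model = recnet.RecurrentClassifier(spec, seed=0)
        assert model.n_parameters() == recnet.parameter_count(spec)


@pytest.fixture(scope="module")
def model():
    return recnet.RecurrentClassifier(recnet.proposed_model(4, 16, 2), seed=1)


class TestPredictProba:

    def test_rows_sum_to_one(self, model):
        X = np.random.default_rng(0).standard_normal((9, 16, 4)).astype(np.float32)
        proba = model.predict_proba(X)
        assert proba.shape == (9, 2)
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_rows_get_identical_outputs(self, model):
        x = np.random.default_rng(1).standard_normal((1, 16, 4)).astype(np.float32)
        X = np.concatenate([x, x], axis=0)
        proba = model.predict_proba(X)
        np.testing.assert_array_equal(proba[0], proba[1])

    def test_batch_permutation_invariance(self, model):
        X = np.random.default_rng(2).standard_normal((7, 16, 4)).astype(np.float32)
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        np.testing.assert_allclose(model.predict_proba(X)[perm],
                                   model.predict_proba(X[perm]), atol=1e-6)

    def test_zeroed_head_gives_uniform_probabilities(self, model):
        head = model.layers[-1]
        head.W[...] = 0.0
        head.b[...] = 0.0
        X = np.random.default_rng(3).standard_normal((5, 16, 4)).astype(np.float32)
        np.testing.assert_allclose(model.predict_proba(X), 0.5, atol=1e-12)

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValidationError):
            model.predict_proba(np.zeros((3, 16, 5), np.float32))

    def test_time_reversed_input_keeps_shape_contract(self, model):
        X = np.random.default_rng(4).standard_normal((3, 16, 4)).astype(np.float32)
        assert model.predict_proba(X[:, ::-1]).shape == model.predict_proba(X).shape


class TestTraining:
    def test_learns_separable_data(self):
        """Amplitude-separated classes reach >= 0.95 training accuracy in 5 epochs."""
        X, y = separable_batch()
        spec = recnet.proposed_model(4, 16, 2)
        model, history = recnet.train(spec, X, y, recnet.TrainConfig(seed=0))
        final_acc = (model.predict(X) == y).mean()
        assert final_acc >= 0.95
        assert history["loss"][0] > history["loss"][-1]

    def test_shuffled_labels_stay_near_chance(self):
        """Label permutation destroys the signal: held-out accuracy ~ majority rate."""
        X, y = separable_batch(n=160, seed=1)
        y_shuffled = np.random.default_rng(2).permutation(y)
        X_test, y_test = separable_batch(n=80, seed=3)
        spec = recnet.proposed_model(4, 16, 2)
        model, _ = recnet.train(spec, X, y_shuffled, recnet.TrainConfig(seed=0))
        acc = (model.predict(X_test) == y_test).mean()
        majority = max(y_test.mean(), 1 - y_test.mean())
        assert acc <= majority + 0.1

    def test_same_seed_identical_history(self):
        X, y = separable_batch(n=64)
        spec = recnet.proposed_model(4, 16, 2)
        _, h1 = recnet.train(spec, X, y, recnet.TrainConfig(seed=4, epochs=2))
        _, h2 = recnet.train(spec, X, y, recnet.TrainConfig(seed=4, epochs=2))
        assert h1 == h2

    def test_beats_null_by_margin_over_paired_seeds(self):
        """Real-label training beats shuffled-label training by >= 0.3 accuracy."""
        margins = []
        for seed in range(5):
            X, y = separable_batch(n=120, seed=seed)
            X_test, y_test = separable_batch(n=60, seed=100 + seed)
            spec = recnet.proposed_model(4, 16, 2)
            real, _ = recnet.train(spec, X, y, recnet.TrainConfig(seed=seed))
            null, _ = recnet.train(
                spec, X, np.random.default_rng(seed).permutation(y),
                recnet.TrainConfig(seed=seed))
            margins.append((real.predict(X_test) == y_test).mean()
                           - (null.predict(X_test) == y_test).mean())
        assert np.mean(margins) >= 0.3

    def test_label_shape_and_range_validation(self):
        X, y = separable_batch(n=16)
        spec = recnet.proposed_model(4, 16, 2)
        model = recnet.RecurrentClassifier(spec, seed=0)
        with pytest.raises(ValidationError):
            model.fit(X, y[:-1])
        with pytest.raises(ValidationError):
            model.fit(X, y + 5)

    def test_heterogeneous_input_shape_rejected(self):
        spec = recnet.proposed_model(4, 16, 2)
        model = recnet.RecurrentClassifier(spec, seed=0)
        with pytest.raises(ValidationError):
            model.fit(np.zeros((8, 12, 4), np.float32), np.zeros(8, int))

    def test_weights_round_trip(self, tmp_path):
        X, y = separable_batch(n=32)
        spec = recnet.proposed_model(4, 16, 2)
        model, _ = recnet.train(spec, X, y, recnet.TrainConfig(seed=0, epochs=1))
        model.save_weights(tmp_path / "w.npz")
        clone = recnet.RecurrentClassifier(spec, seed=99)
        clone.load_weights(tmp_path / "w.npz")
        np.testing.assert_array_equal(model.predict_proba(X), clone.predict_proba(X))


class TestSequenceBatching:
    def test_transpose_and_scale(self, small_dataset):
        from eegaffect import segmentation

        segs = segmentation.segment_trial(
            small_dataset[0], segmentation.SegmentationSpec(64, 64))
        X = recnet.as_sequence_batch(segs, decimation=1, scale=0.5)
        assert X.shape == (len(segs), 64, small_dataset.n_channels)
        np.testing.assert_allclose(
            X[0], 0.5 * segs[0].signal.T.astype(np.float32), rtol=1e-6)

    def test_decimation_average_pools(self, small_dataset):
        from eegaffect import segmentation

        segs = segmentation.segment_trial(
            small_dataset[0], segmentation.SegmentationSpec(64, 64))
        X = recnet.as_sequence_batch(segs, decimation=8, scale=1.0)
        assert X.shape[1] == 8
        manual = segs[0].signal[:, :8].mean(axis=1)
        np.testing.assert_allclose(X[0, 0], manual, rtol=1e-5)

    def test_indivisible_decimation_rejected(self, small_dataset):
        from eegaffect import segmentation

        segs = segmentation.segment_trial(
            small_dataset[0], segmentation.SegmentationSpec(60, 60))
        with pytest.raises(ValidationError):
            recnet.as_sequence_batch(segs, decimation=8)
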