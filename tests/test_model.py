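import numpy as np
import pytest

from cqtnet import (
    ArchitectureConfig,
    TrainConfig,
    build_model,
    load_model,
    predict_proba,
    save_model,
    train,
)
from cqtnet.nn.layers import Conv1d, softmax
from cqtnet.nn.model import ConfigurationError


class TestArchitecture:
    def test_shape_chain(self):
        """Valid conv + floor pooling: 1792 -> 861 -> 406 -> 188 -> 89."""
        chain = ArchitectureConfig().shape_chain()
        assert chain == [1792, 861, 406, 188, 89]

    def test_flatten_length_is_4450(self):
        assert ArchitectureConfig().flatten_len == 4450

    def test_input_len_1793_still_89_but_1808_fails(self):
        assert ArchitectureConfig(input_len=1793).shape_chain()[-1] == 89
        with pytest.raises(ConfigurationError, match="90"):
            ArchitectureConfig(input_len=1808)

    def test_kernel_longer_than_input_fails(self):
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(input_len=60)

    def test_mismatched_hyperparameter_lists_fail(self):
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(conv_filters=(70, 50, 30))

    def test_branch_audit(self):
        """5 weight-independent branches of 4 conv blocks each, identical
        parameter counts, merged feature width 50."""
        model = build_model(seed=0)
        assert len(model.branches) == 5
        counts = []
        for blocks in model.branches:
            convs = [l for l in blocks if isinstance(l, Conv1d)]
            assert len(convs) == 4
            counts.append(sum(p.size for l in blocks for p in l.params))
        assert len(set(counts)) == 1
        assert model.config.merged_features == 50
        # branches are independent parameter arrays, not views
        b0 = model.branches[0][0].w
        b1 = model.branches[1][0].w
        assert b0 is not b1 and not np.array_equal(b0, b1)

    def test_forward_emits_normalized_softmax(self):
        model = build_model(seed=0)
        x = np.random.default_rng(0).normal(size=(3, 5, 1792)).astype(np.float32)
        probs = softmax(model.forward(x))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_flattened_vector_length_from_forward_pass(self):
        model = build_model(seed=0)
        x = np.zeros((1, 5, 1792), dtype=np.float32)
        model.forward(x)
        assert model._flat_shape[1] * model._flat_shape[2] == 4450


class TestTraining:
    def test_separable_data_fit_below_point_three(self, trained_separable):
        """64 strongly separated noiseless segments, 30 epochs: the final
        training cross-entropy must be far below the chance level ln(2)."""
        fitted, _, _ = trained_separable
        assert fitted.training_log[-1]["train_loss"] < 0.3

    def test_loss_does_not_diverge(self, trained_separable):
        fitted, _, _ = trained_separable
        log = fitted.training_log
        assert log[-1]["train_loss"] <= log[0]["train_loss"]
        assert all(np.isfinite(e["train_loss"]) for e in log)

    def test_held_out_deceptive_probability_above_half(self, trained_separable):
        fitted, _, held_out = trained_separable
        for seg in held_out:
            p = predict_proba(fitted, seg)
            assert 0.0 <= p <= 1.0
            if seg.label == "deceptive":
                assert p > 0.5
            else:
                assert p < 0.5

    def test_single_class_data_rejected(self, tiny_dataset):
        segments, _ = tiny_dataset
        only_deceptive = [s for s in segments if s.label == "deceptive"]
        with pytest.raises(ValueError, match="both classes"):
            train(build_model(seed=0), only_deceptive,
                  TrainConfig(max_epochs=1, validation_fraction=0.0))

    def test_training_is_seeded_and_repeatable(self, tiny_dataset):
        segments, _ = tiny_dataset
        cfg = TrainConfig(max_epochs=2, validation_fraction=0.0, seed=3)
        a = train(build_model(seed=1), segments, cfg)
        b = train(build_model(seed=1), segments, cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)
        assert a.training_log == b.training_log

    def test_input_model_left_untouched(self, tiny_dataset):
        segments, _ = tiny_dataset
        model = build_model(seed=1)
        before = [p.copy() for p in model.parameters()]
        train(model, segments, TrainConfig(max_epochs=1, validation_fraction=0.0))
        for p, b in zip(model.parameters(), before):
            np.testing.assert_array_equal(p, b)


class TestInference:
    def test_predict_is_deterministic(self, trained_separable):
        fitted, _, held_out = trained_separable
        seg = held_out[0]
        assert predict_proba(fitted, seg) == predict_proba(fitted, seg)

    def test_two_class_masses_sum_to_one(self, trained_separable):
        fitted, _, held_out = trained_separable
        x = held_out[0].x[None].astype(np.float32)
        probs = softmax(fitted.predict_logits(x).astype(np.float64))
        assert probs[0].sum() == pytest.approx(1.0, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        model = build_model(seed=0)
        with pytest.raises(ValueError, match="expected input"):
            model.forward(np.zeros((1, 5, 100), dtype=np.float32))


class TestSerialization:
    def test_save_load_round_trip(self, trained_separable, tmp_path):
        fitted, _, held_out = trained_separable
        path = save_model(fitted, tmp_path / "model.npz")
        back = load_model(path)
        assert back.config == fitted.config
        assert back.training_log == fitted.training_log
        np.testing.assert_array_equal(
            predict_proba(back, held_out), predict_proba(fitted, held_out)
        )
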