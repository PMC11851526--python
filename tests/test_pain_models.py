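"""Windowing, Transformer/LSTM pain classifiers, and decision rules."""

import numpy as np
import pytest

import painmesh as pm
from painmesh.exceptions import ContractViolationError, InvalidInputError


def seqs_of(lengths, na=8, label=0):
    rng = np.random.default_rng(0)
    return [(rng.random((L, na)), label, f"s{i}", f"seg{i}")
            for i, L in enumerate(lengths)]


class TestWindowing:
    def test_exact_fit_single_window(self):
        w = pm.window_segments(seqs_of([350]), T=350)
        assert len(w) == 1
        assert w[0].mask.all()

    def test_short_segment_padded_with_mask(self):
        w = pm.window_segments(seqs_of([200]), T=350)
        assert len(w) == 1
        assert w[0].values.shape == (350, 8)
        assert w[0].mask[:200].all() and not w[0].mask[200:].any()
        assert np.all(w[0].values[200:] == 0.0)

    def test_long_segment_stride_and_tail_rule(self):
        # 900 frames: windows at 0 and 350; tail of 200 >= 175 adds one
        # right-aligned window at 550
        w = pm.window_segments(seqs_of([900]), T=350)
        assert len(w) == 3
        # 500 frames: tail of 150 < 175, no extra window
        w = pm.window_segments(seqs_of([500]), T=350)
        assert len(w) == 1

    def test_too_short_segment_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            w = pm.window_segments(seqs_of([5, 40]), T=350)
        assert len(w) == 1

    def test_windows_inherit_label_and_subject(self):
        w = pm.window_segments(seqs_of([400], label=1), T=350)
        assert all(x.label == 1 and x.subject_id == "s0" for x in w)


@pytest.fixture(scope="module")
def separable_windows():
    """Pain windows carry sustained activation of a fixed AU subset,
    non-pain windows only sparse noise: separable by construction."""
    rng = np.random.default_rng(7)
    windows = []
    T, na = 60, 8
    for i in range(60):
        label = int(i % 4 == 0)
        v = (rng.random((T, na)) < 0.05).astype(float)
        if label:
            start = rng.integers(0, T - 30)
            v[start:start + 30, [1, 3, 7]] = 1.0  # sustained pain pattern
        windows.append(pm.AUSequenceWindow(v, np.ones(T, dtype=bool), label,
                                           subject_id=f"s{i // 4}",
                                           segment_id=f"seg{i}"))
    return windows


SMALL_TRANSFORMER = dict(projection_dim=32, num_heads=4, num_encoder_layers=2,
                         ffn_dim=64, mlp_hidden=32, dropout=0.1,
                         learning_rate=1e-3, max_epochs=20, seed=0)
SMALL_LSTM = dict(hidden_dim=32, mlp_hidden=32, learning_rate=1e-3,
                  max_epochs=20, seed=0)


class TestTraining:
    @pytest.mark.parametrize("config", [
        pm.PainTransformerConfig(**SMALL_TRANSFORMER),
        pm.PainLSTMConfig(**SMALL_LSTM),
    ], ids=["transformer", "lstm"])
    def test_heldout_accuracy_on_separable_fixture(self, separable_windows,
                                                   config):
        train = [w for w in separable_windows if int(w.subject_id[1:]) < 10]
        test = [w for w in separable_windows if int(w.subject_id[1:]) >= 10]
        model = pm.train_pain_model(train, config)
        pred = (model.predict_proba(test) >= 0.5).astype(int)
        acc = np.mean(pred == [w.label for w in test])
        majority = np.mean([w.label == 0 for w in test])
        assert acc >= 0.95
        assert acc > majority

    def test_single_class_training_rejected(self, separable_windows):
        only_neg = [w for w in separable_windows if w.label == 0]
        with pytest.raises(ContractViolationError):
            pm.train_pain_model(only_neg, pm.PainLSTMConfig(**SMALL_LSTM))

    def test_config_echo(self):
        cfg = pm.PainTransformerConfig()
        assert cfg.projection_dim == 1024
        assert cfg.num_heads == 4
        assert cfg.num_encoder_layers == 2
        assert cfg.learning_rate == 1e-5
        assert cfg.batch_size == 16
        assert cfg.max_epochs == 150
        model = pm.PainTransformerModel(8, pm.PainTransformerConfig(
            projection_dim=16, num_heads=4, num_encoder_layers=2, ffn_dim=16,
            mlp_hidden=8))
        assert len(model.layers) == 2
        assert model.layers[0].attn.h == 4
        lcfg = pm.PainLSTMConfig()
        assert (lcfg.num_layers, lcfg.hidden_dim, lcfg.learning_rate) == (2, 512, 1e-3)

    def test_projection_must_divide_heads(self):
        with pytest.raises(InvalidInputError):
            pm.PainTransformerConfig(projection_dim=30, num_heads=4)


class TestPredict:
    def make_tiny_model(self):
        return pm.PainTransformerModel(4, pm.PainTransformerConfig(
            projection_dim=8, num_heads=2, num_encoder_layers=1, ffn_dim=8,
            mlp_hidden=4, dropout=0.0, seed=1))

    def test_round_rule(self):
        assert pm.pain_label(0.49) == 0
        assert pm.pain_label(0.51) == 1
        assert pm.pain_label(0.5) == 1

    def test_zeroed_head_gives_half_probability(self):
        model = self.make_tiny_model()
        model.head.fc1.W.value[:] = 0.0
        model.head.fc1.b.value[:] = 0.0
        model.head.fc2.W.value[:] = 0.0
        model.head.fc2.b.value[:] = 0.0
        w = pm.AUSequenceWindow(np.random.default_rng(0).random((6, 4)),
                                np.ones(6, dtype=bool), 0)
        assert pm.predict_pain(model, w) == 0.5

    def test_frame_permutation_changes_output(self):
        """Positional encoding breaks permutation invariance."""
        model = self.make_tiny_model()
        rng = np.random.default_rng(2)
        v = rng.random((6, 4))
        w1 = pm.AUSequenceWindow(v, np.ones(6, dtype=bool), 0)
        v2 = v.copy()
        v2[[0, 3]] = v2[[3, 0]]
        w2 = pm.AUSequenceWindow(v2, np.ones(6, dtype=bool), 0)
        assert pm.predict_pain(model, w1) != pm.predict_pain(model, w2)

    def test_na_mismatch_rejected(self):
        model = self.make_tiny_model()
        w = pm.AUSequenceWindow(np.zeros((6, 5)), np.ones(6, dtype=bool), 0)
        with pytest.raises(InvalidInputError):
            pm.predict_pain(model, w)

    def test_encode_shape_and_padding_constant_tail(self):
        """encode returns (T, d); a fully-padded tail cannot influence the
        representation at the last real frame."""
        model = self.make_tiny_model()
        rng = np.random.default_rng(3)
        v = rng.random((6, 4))
        mask = np.array([True] * 4 + [False] * 2)
        w = pm.AUSequenceWindow(v, mask, 0)
        z = pm.encode_sequence(model, w)
        assert z.shape == (6, 8)
        v2 = v.copy()
        v2[4:] = 99.0  # padded content differs
        z2 = pm.encode_sequence(model, pm.AUSequenceWindow(v2, mask, 0))
        assert np.allclose(z[:4], z2[:4], atol=1e-10)


class TestSegmentDecision:
    def test_majority_and_tie_rules(self):
        assert pm.segment_decision([1, 1, 0]) == 1
        assert pm.segment_decision([0, 0, 1]) == 0
        assert pm.segment_decision([0, 1]) == 1  # tie -> pain
        assert pm.segment_decision([0]) == 0
        with pytest.raises(InvalidInputError):
            pm.segment_decision([])


class TestCheckpoints:
    @pytest.mark.parametrize("config", [
        pm.PainTransformerConfig(projection_dim=8, num_heads=2,
                                 num_encoder_layers=1, ffn_dim=8,
                                 mlp_hidden=4, dropout=0.0, seed=1),
        pm.PainLSTMConfig(num_layers=1, hidden_dim=8, mlp_hidden=4, seed=1),
    ], ids=["transformer", "lstm"])
    def test_roundtrip_preserves_predictions(self, config, tmp_path):
        if isinstance(config, pm.PainTransformerConfig):
            model = pm.PainTransformerModel(4, config)
        else:
            model = pm.PainLSTMModel(4, config)
        w = pm.AUSequenceWindow(np.random.default_rng(0).random((6, 4)),
                                np.ones(6, dtype=bool), 0)
        pm.save_pain_model(model, tmp_path / "ck")
        loaded = pm.load_pain_model(tmp_path / "ck")
        assert pm.predict_pain(loaded, w) == pm.predict_pain(model, w)

    def test_prediction_export_csv(self, tmp_path):
        windows = [pm.AUSequenceWindow(np.zeros((4, 2)), np.ones(4, bool), 1,
                                       subject_id="sA", segment_id="segA"),
                   pm.AUSequenceWindow(np.zeros((4, 2)), np.ones(4, bool), 0,
                                       subject_id="sB", segment_id="segB")]
        pm.export_predictions_csv(windows, [0.9, 0.2], tmp_path / "p.csv")
        lines = (tmp_path / "p.csv").read_text().strip().splitlines()
        assert lines[0] == "segment_id,subject_id,probability,label"
        assert lines[1].startswith("segA,sA,0.9") and lines[1].endswith(",1")
        assert lines[2].endswith(",0")
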