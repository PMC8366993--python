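"""Architecture conformance, sequence assembly, network numerics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from somnet import _nn
from somnet.model import (
    ModelConfig,
    RecordingPatterns,
    SleepStager,
    assemble_sequence,
    load_checkpoint,
    save_checkpoint,
    variant_grid,
)
from somnet.psg_io import ValidationError


class TestModelConfig:
    def test_variant_grid_has_exactly_14_unique_names(self):
        names = [c.name for c in variant_grid()]
        assert len(names) == 14 and len(set(names)) == 14
        assert "CNN_1" in names and "CNN_LSTM_F_7" in names
        assert "CNN_LSTM_1" not in names

    @pytest.mark.parametrize(
        "name, mode, L, filtering",
        [
            ("CNN_1", "CNN", 1, False),
            ("CNN_F_3", "CNN", 3, True),
            ("CNN_LSTM_5", "CNN_LSTM", 5, False),
            ("CNN_LSTM_F_7", "CNN_LSTM", 7, True),
        ],
    )
    def test_name_round_trip(self, name, mode, L, filtering):
        cfg = ModelConfig.from_name(name)
        assert (cfg.mode, cfg.L, cfg.filtering) == (mode, L, filtering)
        assert cfg.name == name

    def test_filter_doubling(self):
        assert ModelConfig().filters_per_block == (8, 16, 32)

    def test_invalid_variants_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(mode="CNN_LSTM", L=1)
        with pytest.raises(ValidationError):
            ModelConfig(mode="CNN", L=2)
        with pytest.raises(ValidationError):
            ModelConfig.from_name("CNN_LSTM_1")


class TestAssembleSequence:
    def test_printed_worked_examples(self):
        assert assemble_sequence(10, 3, 100) == [9, 10, 11]
        assert assemble_sequence(10, 4, 100) == [8, 9, 10, 11]

    def test_edge_replication(self):
        assert assemble_sequence(1, 5, 100) == [1, 1, 1, 2, 3]
        assert assemble_sequence(100, 5, 100) == [98, 99, 100, 100, 100]
        assert assemble_sequence(7, 1, 50) == [7]

    def test_out_of_range_center_rejected(self):
        with pytest.raises(IndexError):
            assemble_sequence(0, 3, 10)
        with pytest.raises(IndexError):
            assemble_sequence(11, 3, 10)

    def test_exhaustive_against_ceil_floor_enumeration(self):
        for L in range(1, 10):
            for M in range(1, 51):
                for k in range(1, M + 1):
                    lo = k - math.ceil((L - 1) / 2)
                    hi = k + math.floor((L - 1) / 2)
                    expected = [min(max(i, 1), M) for i in range(lo, hi + 1)]
                    got = assemble_sequence(k, L, M)
                    assert got == expected and len(got) == L


class TestConvGradients:
    def test_finite_difference_gradcheck(self, rng):
        x = rng.normal(size=(2, 2, 1, 9))
        w = rng.normal(size=(3, 2, 4))
        dy = rng.normal(size=(2, 3, 1, 9))
        dx, dw = _nn.conv1d_same_grads(x, w, dy)
        eps = 1e-6
        for idx in [(0, 1, 0, 3), (1, 0, 0, 0), (1, 1, 0, 8)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = ((_nn.conv1d_same(xp, w) - _nn.conv1d_same(xm, w)) * dy).sum() / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=1e-5, abs=1e-7)
        for idx in [(0, 0, 0), (2, 1, 3)]:
            wp, wm = w.copy(), w.copy()
            wp[idx] += eps
            wm[idx] -= eps
            num = ((_nn.conv1d_same(x, wp) - _nn.conv1d_same(x, wm)) * dy).sum() / (2 * eps)
            assert dw[idx] == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestFeatureExtractor:
    def test_single_epoch_shapes(self, rng):
        model = SleepStager(ModelConfig(mode="CNN", L=1), seed=0)
        x = rng.normal(size=(2, 1, 4, 3000)).astype(np.float32)
        h = x
        shapes = []
        for conv, relu, bn, pool in model.blocks:
            h = pool.forward(bn.forward(relu.forward(conv.forward(h))))
            shapes.append(h.shape[1:])
        assert shapes == [(8, 4, 1500), (16, 4, 750), (32, 4, 375)]
        assert model.flat_size == 48000
        assert model.features(x).shape == (2, 50)

    def test_sequence_input_shapes(self, rng):
        model = SleepStager(ModelConfig(mode="CNN", L=3), seed=0)
        x = rng.normal(size=(1, 1, 4, 9000)).astype(np.float32)
        assert model.flat_size == 32 * 4 * 1125
        assert model.features(x).shape == (1, 50)

    def test_indivisible_input_width_rejected(self):
        # 3000 is not divisible by 7^3: the three poolings cannot apply
        with pytest.raises(ValidationError):
            SleepStager(ModelConfig(mode="CNN", L=1, pool=7), seed=0)

    def test_parameter_count_is_config_arithmetic(self):
        for cfg in (ModelConfig(mode="CNN", L=1), ModelConfig(mode="CNN_LSTM", L=3)):
            model = SleepStager(cfg, seed=0)
            conv = sum(
                o * i * 100 + o
                for i, o in [(1, 8), (8, 16), (16, 32)]
            )
            bn = 2 * (8 + 16 + 32)
            feat = model.flat_size * 50 + 50
            if cfg.mode == "CNN":
                head = 50 * 5 + 5
            else:
                head = (50 * 400 + 100 * 400 + 400) + (100 * 5 + 5)
            assert model.n_parameters() == conv + bn + feat + head


class TestHeads:
    def test_posteriors_sum_to_one(self, rng, tiny_site):
        for cfg in (ModelConfig(mode="CNN", L=1), ModelConfig(mode="CNN_LSTM", L=3)):
            model = SleepStager(cfg, seed=3)
            proba = model.predict_proba(tiny_site[0])
            assert proba.shape == (len(tiny_site[0]), 5)
            np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
            assert (proba >= 0).all() and (proba <= 1).all()

    def test_zero_logits_give_uniform_posterior(self):
        np.testing.assert_allclose(
            _nn.softmax(np.zeros((1, 5))), np.full((1, 5), 0.2)
        )

    def test_inference_is_deterministic_despite_dropout(self, tiny_site):
        model = SleepStager(ModelConfig(mode="CNN", L=1), seed=1)
        p1 = model.predict_proba(tiny_site[0])
        p2 = model.predict_proba(tiny_site[0])
        np.testing.assert_array_equal(p1, p2)

    def test_dropout_active_only_in_training(self, rng):
        drop = _nn.Dropout(0.5)
        drop.reseed(7)
        x = np.ones((4, 50), dtype=np.float32)
        assert not np.array_equal(drop.forward(x, train=True), x)
        np.testing.assert_array_equal(drop.forward(x, train=False), x)

    def test_lstm_is_order_sensitive(self, rng):
        lstm = _nn.LSTM(50, 100, rng=np.random.default_rng(0))
        seq = rng.normal(size=(1, 5, 50)).astype(np.float32)
        h1 = lstm.forward(seq)
        h2 = lstm.forward(seq[:, ::-1, :].copy())
        assert np.abs(h1 - h2).max() > 1e-6

    def test_lstm_consumes_whole_sequence(self, rng):
        lstm = _nn.LSTM(50, 100, rng=np.random.default_rng(0))
        seq = rng.normal(size=(1, 5, 50)).astype(np.float32)
        seq2 = seq.copy()
        seq2[:, 0, :] += 1.0  # perturb the earliest element
        assert np.abs(lstm.forward(seq) - lstm.forward(seq2)).max() > 1e-7


class TestPrediction:
    def test_argmax_defines_the_stage(self, tiny_site):
        from somnet.psg_io import AASM_STAGES

        model = SleepStager(ModelConfig(mode="CNN", L=1), seed=5)
        hyp, proba = model.predict_recording(tiny_site[0])
        assert len(hyp.stages) == len(tiny_site[0])
        for stage, row in zip(hyp.stages, proba):
            assert stage == AASM_STAGES[int(np.argmax(row))]

    def test_empty_pattern_list_rejected(self):
        model = SleepStager(ModelConfig(mode="CNN", L=1), seed=0)
        empty = RecordingPatterns("e", np.zeros((0, 4, 3000), np.float32), [])
        with pytest.raises(ValidationError):
            model.predict_proba(empty)

    def test_checkpoint_round_trip(self, tmp_path, tiny_site):
        model = SleepStager(ModelConfig(mode="CNN_LSTM", L=3), seed=9)
        save_checkpoint(model, tmp_path / "m.npz", origin="tiny")
        clone, origin = load_checkpoint(tmp_path / "m.npz")
        assert origin == "tiny" and clone.cfg == model.cfg
        np.testing.assert_array_equal(
            clone.predict_proba(tiny_site[0]), model.predict_proba(tiny_site[0])
        )


@given(st.integers(1, 9), st.integers(1, 50))
def test_sequence_length_is_always_L(L, M):
    for k in range(1, M + 1):
        assert len(assemble_sequence(k, L, M)) == L
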