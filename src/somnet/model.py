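"""CNN and CNN-LSTM sleep-stage classifiers.

The shared feature extractor is a stack of N=3 operational blocks
(1x100 temporal convolution with zero padding -> ReLU -> batch
normalization -> 1x2 average pooling), doubling the filter count per block
from 8, followed by a fully-connected output step that reduces the feature
space to 50 values per epoch.

In CNN-only mode the 50-vector goes through ReLU -> dropout(0.5) ->
dense(5) -> softmax.  In CNN-LSTM mode, per-epoch 50-vectors are arranged
into the context sequence S(k) around the epoch under evaluation and
consumed by a unidirectional LSTM (100 hidden units) whose final state
feeds a dense softmax layer; the posterior refers to the center epoch k.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from typing import Optional, Sequence

import numpy as np

from . import _nn
from .preprocess import EPOCH_SAMPLES, N_INPUT_CHANNELS, standardize
from .psg_io import AASM_STAGES, STAGE_TO_INDEX, UNKNOWN, Hypnogram, ValidationError

N_CLASSES = 5


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """One of the 14 tested architecture variants.

    mode "CNN" classifies a (possibly concatenated) raw input window;
    "CNN_LSTM" classifies the center epoch of an epoch-feature sequence.
    The remaining constants are fixed across the whole variant grid.
    """

    mode: str = "CNN"
    L: int = 1
    filtering: bool = False
    n_blocks: int = 3
    base_filters: int = 8
    kernel_time: int = 100
    pool: int = 2
    feature_size: int = 50
    lstm_hidden: int = 100
    n_classes: int = N_CLASSES
    dropout_p: float = 0.5

    def __post_init__(self):
        if self.mode not in ("CNN", "CNN_LSTM"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        valid_L = (1, 3, 5, 7) if self.mode == "CNN" else (3, 5, 7)
        if self.L not in valid_L:
            raise ValidationError(
                f"L={self.L} not in the tested grid for mode {self.mode}"
            )

    @property
    def name(self) -> str:
        f = "_F" if self.filtering else ""
        base = "CNN" if self.mode == "CNN" else "CNN_LSTM"
        return f"{base}{f}_{self.L}"

    @property
    def filters_per_block(self) -> tuple[int, ...]:
        return tuple(self.base_filters * 2 ** k for k in range(self.n_blocks))

    @property
    def input_width(self) -> int:
        """Time samples consumed by the CNN in one forward pass."""
        return EPOCH_SAMPLES * (self.L if self.mode == "CNN" else 1)

    @classmethod
    def from_name(cls, name: str) -> "ModelConfig":
        m = name.strip().upper()
        try:
            parts = m.split("_")
            L = int(parts[-1])
            filtering = "F" in parts[:-1]
            mode = "CNN_LSTM" if "LSTM" in parts else "CNN"
            cfg = cls(mode=mode, L=L, filtering=filtering)
        except (ValueError, IndexError) as exc:
            raise ValidationError(f"cannot parse variant name {name!r}") from exc
        if cfg.name != m:
            raise ValidationError(f"cannot parse variant name {name!r}")
        return cfg


def variant_grid() -> list[ModelConfig]:
    """The full 14-variant grid (CNN L in {1,3,5,7}, CNN-LSTM L in {3,5,7},
    each with and without the filtering step)."""
    out = []
    for filtering in (False, True):
        for L in (1, 3, 5, 7):
            out.append(ModelConfig(mode="CNN", L=L, filtering=filtering))
        for L in (3, 5, 7):
            out.append(ModelConfig(mode="CNN_LSTM", L=L, filtering=filtering))
    return out


# ---------------------------------------------------------------------------
# Epoch-sequence assembly
# ---------------------------------------------------------------------------

def assemble_sequence(k: int, L: int, M: int) -> list[int]:
    """1-based epoch indices of the sequence S(k) of length L.

    Offsets run from k - ceil((L-1)/2) to k + floor((L-1)/2); indices
    outside [1, M] are replaced by the nearest valid epoch (edge
    replication), keeping the sequence length fixed at recording boundaries.
    """
    if not 1 <= k <= M:
        raise IndexError(f"epoch index {k} outside [1, {M}]")
    if L < 1:
        raise ValidationError("L must be >= 1")
    lo = k - math.ceil((L - 1) / 2)
    return [min(max(i, 1), M) for i in range(lo, lo + L)]


# ---------------------------------------------------------------------------
# Data container consumed by models and the trainer
# ---------------------------------------------------------------------------

class RecordingPatterns:
    """Raw 30 s patterns of one recording plus integer stage labels.

    ``labels`` uses the fixed class order W, N1, N2, N3, R (0..4); UNKNOWN
    epochs carry -1 and are excluded from training and scoring.
    """

    def __init__(self, rec_id: str, patterns: np.ndarray, stages: Sequence[str]):
        patterns = np.asarray(patterns, dtype=np.float32)
        if patterns.ndim != 3 or patterns.shape[1:] != (N_INPUT_CHANNELS, EPOCH_SAMPLES):
            raise ValidationError("patterns must be (M, 4, 3000)")
        if len(stages) != patterns.shape[0]:
            raise ValidationError("labels and patterns differ in length")
        self.rec_id = rec_id
        self.patterns = patterns
        self.stages = list(stages)
        self.labels = np.array(
            [STAGE_TO_INDEX.get(s, -1) for s in stages], dtype=np.int64
        )
        self._std: Optional[np.ndarray] = None

    def __len__(self):
        return self.patterns.shape[0]

    @property
    def std_patterns(self) -> np.ndarray:
        """Per-epoch Gaussian-standardized patterns (cached)."""
        if self._std is None:
            x = self.patterns.astype(np.float64)
            m = x.mean(axis=(1, 2), keepdims=True)
            sd = x.std(axis=(1, 2), keepdims=True)
            sd[sd < 1e-8] = np.inf  # zero-variance guard -> zero pattern
            self._std = ((x - m) / sd).astype(np.float32)
        return self._std


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class SleepStager:
    """A CNN or CNN-LSTM variant with its weights.

    All randomness (initialization, dropout) derives from ``seed``; two
    stagers built from the same (config, seed) are bit-identical.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        w = cfg.input_width
        if w % (cfg.pool ** cfg.n_blocks) != 0:
            raise ValidationError("input width must be divisible by 8")

        self.blocks = []
        in_maps = 1
        for n_f in cfg.filters_per_block:
            self.blocks.append(
                (
                    _nn.ConvTime(in_maps, n_f, cfg.kernel_time, rng),
                    _nn.ReLU(),
                    _nn.BatchNormMaps(n_f),
                    _nn.AvgPoolTime(),
                )
            )
            in_maps = n_f
        self.flat_size = in_maps * N_INPUT_CHANNELS * (w // cfg.pool ** cfg.n_blocks)
        self.fc_feat = _nn.Dense(self.flat_size, cfg.feature_size, rng)

        if cfg.mode == "CNN":
            self.head_relu = _nn.ReLU()
            self.head_drop = _nn.Dropout(cfg.dropout_p)
            self.fc_out = _nn.Dense(cfg.feature_size, cfg.n_classes, rng, scale="glorot")
            self.lstm = None
        else:
            self.lstm = _nn.LSTM(cfg.feature_size, cfg.lstm_hidden, rng)
            self.fc_out = _nn.Dense(cfg.lstm_hidden, cfg.n_classes, rng, scale="glorot")
            self.head_relu = self.head_drop = None

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        for blk in self.blocks:
            yield from blk
        yield self.fc_feat
        if self.cfg.mode == "CNN":
            yield self.head_relu
            yield self.head_drop
        else:
            yield self.lstm
        yield self.fc_out

    def parameters(self):
        """List of (param, grad) array pairs, in a stable order."""
        out = []
        for layer in self._layers():
            out.extend(zip(layer.params, layer.grads))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def reseed_dropout(self, seed: int) -> None:
        if self.head_drop is not None:
            self.head_drop.reseed(seed)

    def snapshot(self) -> list[np.ndarray]:
        state = [p.copy() for p, _ in self.parameters()]
        for layer in self._layers():
            if isinstance(layer, _nn.BatchNormMaps):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def restore(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for (p, _), saved in zip(params, state):
            p[...] = saved
        i = len(params)
        for layer in self._layers():
            if isinstance(layer, _nn.BatchNormMaps):
                layer.running_mean = state[i].copy()
                layer.running_var = state[i + 1].copy()
                i += 2

    # -- forward / backward -------------------------------------------------

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """CNN feature extraction: (B, 1, 4, W) -> (B, 50)."""
        h = x
        for conv, relu, bn, pool in self.blocks:
            h = pool.forward(bn.forward(relu.forward(conv.forward(h, train), train), train), train)
        self._feat_shape = h.shape
        return self.fc_feat.forward(h.reshape(h.shape[0], -1), train)

    def backward_features(self, dfeat: np.ndarray) -> None:
        dh = self.fc_feat.backward(dfeat).reshape(self._feat_shape)
        for bi, (conv, relu, bn, pool) in enumerate(reversed(self.blocks)):
            dh = bn.backward(pool.backward(dh))
            dh = relu.backward(dh)
            if bi == len(self.blocks) - 1:
                # no layer below the first convolution: skip its dx
                _, dw = _nn.conv1d_same_grads(conv._x, conv.w, dh)
                conv.grads[0][...] = dw
                conv.grads[1][...] = dh.sum(axis=(0, 2, 3))
                conv._x = None
            else:
                dh = conv.backward(dh)

    def _head_forward(self, feat: np.ndarray, train: bool) -> np.ndarray:
        h = self.head_relu.forward(feat, train)
        h = self.head_drop.forward(h, train)
        return self.fc_out.forward(h, train)

    def _head_backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.fc_out.backward(dlogits)
        dh = self.head_drop.backward(dh)
        return self.head_relu.backward(dh)

    # -- model input assembly ----------------------------------------------

    def _cnn_inputs(self, rec: RecordingPatterns, ks: np.ndarray) -> np.ndarray:
        """Standardized CNN inputs for 1-based epoch indices ``ks``."""
        if self.cfg.L == 1:
            return rec.std_patterns[ks - 1]
        from .preprocess import build_cnn_sequence_input

        return np.stack(
            [
                build_cnn_sequence_input(rec.patterns, int(k), self.cfg.L).astype(
                    np.float32
                )
                for k in ks
            ]
        )

    # -- batched training step ----------------------------------------------

    def batch_loss(
        self,
        recs: list[RecordingPatterns],
        examples: np.ndarray,
        train: bool = False,
    ) -> float:
        """Cross-entropy on a batch of (recording, epoch) examples.

        In training mode the per-parameter gradients are left in
        ``self.parameters()`` for the optimizer.
        """
        if len(examples) == 0:
            raise ValidationError("empty batch")
        y = np.array([recs[r].labels[k - 1] for r, k in examples], dtype=np.int64)

        if self.cfg.mode == "CNN":
            if self.cfg.L == 1:
                xs = [recs[r].std_patterns[k - 1] for r, k in examples]
            else:
                from .preprocess import build_cnn_sequence_input

                xs = [
                    build_cnn_sequence_input(
                        recs[r].patterns, int(k), self.cfg.L
                    ).astype(np.float32)
                    for r, k in examples
                ]
            x = np.stack(xs)[:, None, :, :]
            feat = self.features(x, train)
            logits = self._head_forward(feat, train)
            loss, dlogits = _nn.cross_entropy(logits, y)
            if train:
                self.backward_features(self._head_backward(dlogits))
            return loss

        # CNN_LSTM: run the shared CNN once per distinct epoch in the batch,
        # then gather the per-example feature sequences.
        L = self.cfg.L
        need = {}
        seq_idx = np.empty((len(examples), L), dtype=np.int64)
        for e, (r, k) in enumerate(examples):
            for j, kk in enumerate(assemble_sequence(int(k), L, len(recs[r]))):
                key = (int(r), int(kk))
                if key not in need:
                    need[key] = len(need)
                seq_idx[e, j] = need[key]
        uniq = list(need.keys())
        x = np.stack([recs[r].std_patterns[k - 1] for r, k in uniq])[:, None, :, :]
        feat_u = self.features(x, train)  # (U, 50)
        seq = feat_u[seq_idx]  # (B, L, 50)
        h = self.lstm.forward(seq, train)
        logits = self.fc_out.forward(h, train)
        loss, dlogits = _nn.cross_entropy(logits, y)
        if train:
            dh = self.fc_out.backward(dlogits)
            dseq = self.lstm.backward(dh)
            dfeat_u = np.zeros_like(feat_u)
            np.add.at(dfeat_u, seq_idx.ravel(), dseq.reshape(-1, feat_u.shape[1]))
            self.backward_features(dfeat_u)
        return loss

    # -- inference ----------------------------------------------------------

    def predict_proba(
        self, rec: RecordingPatterns, batch_size: int = 100
    ) -> np.ndarray:
        """Stage posteriors (M, 5) for every epoch of a recording."""
        M = len(rec)
        if M == 0:
            raise ValidationError("empty pattern list")
        if self.cfg.mode == "CNN":
            out = np.empty((M, N_CLASSES), dtype=np.float64)
            for s in range(0, M, batch_size):
                ks = np.arange(s + 1, min(s + batch_size, M) + 1)
                x = self._cnn_inputs(rec, ks)[:, None, :, :]
                logits = self._head_forward(self.features(x, train=False), False)
                out[s : s + len(ks)] = _nn.softmax(logits.astype(np.float64))
            return out
        feats = np.empty((M, self.cfg.feature_size), dtype=np.float32)
        for s in range(0, M, batch_size):
            x = rec.std_patterns[s : s + batch_size][:, None, :, :]
            feats[s : s + x.shape[0]] = self.features(x, train=False)
        idx = np.array(
            [[i - 1 for i in assemble_sequence(k, self.cfg.L, M)] for k in range(1, M + 1)]
        )
        out = np.empty((M, N_CLASSES), dtype=np.float64)
        for s in range(0, M, batch_size):
            seq = feats[idx[s : s + batch_size]]
            h = self.lstm.forward(seq, train=False)
            logits = self.fc_out.forward(h, train=False)
            out[s : s + seq.shape[0]] = _nn.softmax(logits.astype(np.float64))
        return out

    def predict_recording(
        self, rec: RecordingPatterns, batch_size: int = 100
    ) -> tuple[Hypnogram, np.ndarray]:
        """Hypnogram (argmax stages; ties -> lowest stage index) + posteriors."""
        proba = self.predict_proba(rec, batch_size=batch_size)
        stages = [AASM_STAGES[i] for i in proba.argmax(axis=1)]
        return Hypnogram(stages=stages), proba


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: SleepStager, path, origin: str = "") -> None:
    cfg = dataclasses.asdict(model.cfg)
    meta = json.dumps({"config": cfg, "seed": model.seed, "origin": origin})
    arrays = {f"state_{i}": a for i, a in enumerate(model.snapshot())}
    np.savez(path, meta=np.array(meta), **arrays)


def load_checkpoint(path) -> tuple[SleepStager, str]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        n = len([k for k in z.files if k.startswith("state_")])
        state = [z[f"state_{i}"] for i in range(n)]
    cfg = ModelConfig(**meta["config"])
    model = SleepStager(cfg, seed=meta["seed"])
    model.restore(state)
    return model, meta.get("origin", "")
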