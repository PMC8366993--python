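"""Training protocol: recording-level splits, SGD with stepped learning
rate, five validation evaluations per training epoch, patience-based early
stopping, and full determinism from a seed.

Defaults reproduce the reference protocol: mini-batches of 100 patterns,
plain SGD on cross-entropy, at most 30 training epochs, initial learning
rate 1e-3 divided by 10 every 10 epochs (floor 1e-6), validation loss
evaluated 5 times per epoch, stop after 10 consecutive evaluations without
improvement (two passes over the training data), best-validation weights
restored at the end.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence

import numpy as np

from .model import RecordingPatterns, SleepStager
from .psg_io import AASM_STAGES, ValidationError

logger = logging.getLogger("somnet.training")


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitSpec:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int


def split_dataset(
    recording_ids: Sequence[str], seed: int, min_recordings: int = 5
) -> SplitSpec:
    """Shuffle recordings and split 80/20 train/test, then 20% of the
    training pool to validation.  Splits are by whole recording so that no
    epochs of one recording appear on both sides of a partition.
    """
    ids = list(recording_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("recording ids must be unique")
    if len(ids) < min_recordings:
        raise ValidationError(
            f"need at least {min_recordings} recordings, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_ts = max(1, int(math.floor(0.2 * len(ids) + 0.5)))
    ts = shuffled[:n_ts]
    pool = shuffled[n_ts:]
    n_val = max(1, int(math.ceil(0.2 * len(pool))))
    val = pool[:n_val]
    tr = pool[n_val:]
    if not tr:
        raise ValidationError("training partition is empty")
    return SplitSpec(train_ids=tr, val_ids=val, test_ids=ts, seed=seed)


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------

def lr_at(epoch: int, initial: float = 1e-3, minimum: float = 1e-6) -> float:
    """Stepped schedule: divide by 10 every 10 training epochs (1-based)."""
    if epoch < 1:
        raise ValidationError("epoch is 1-based")
    return max(initial * 10.0 ** (-((epoch - 1) // 10)), minimum)


# ---------------------------------------------------------------------------
# Trainer
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainSettings:
    batch_size: int = 100
    max_epochs: int = 30
    initial_lr: float = 1e-3
    min_lr: float = 1e-6
    evals_per_epoch: int = 5
    patience: int = 10
    improve_tol: float = 1e-5


@dataclasses.dataclass
class TrainState:
    epoch: int = 0
    best_val_loss: float = math.inf
    best_eval: int = 0
    n_evals: int = 0
    evals_since_improve: int = 0
    stopped_early: bool = False
    history: list = dataclasses.field(default_factory=list)  # (step, tr, val)


def effective_iterations(state: TrainState) -> int:
    """Completed training epochs at stop (the 'training iterations' count)."""
    return state.epoch


def _training_examples(recs: list[RecordingPatterns]) -> np.ndarray:
    """(rec_index, 1-based epoch) pairs for all scored (non-UNKNOWN) epochs."""
    pairs = [
        (r, k + 1)
        for r, rec in enumerate(recs)
        for k in range(len(rec))
        if rec.labels[k] >= 0
    ]
    return np.array(pairs, dtype=np.int64)


def train_model(
    model: SleepStager,
    train_recs: list[RecordingPatterns],
    val_recs: list[RecordingPatterns],
    seed: int,
    settings: Optional[TrainSettings] = None,
) -> TrainState:
    """SGD training with early stopping; reproducible from (model, data, seed).

    The model is trained in place; on return its weights are those of the
    best validation evaluation.
    """
    s = settings or TrainSettings()
    train_ex = _training_examples(train_recs)
    val_ex = _training_examples(val_recs)
    if len(train_ex) == 0:
        raise ValidationError("no scored training epochs")
    if len(val_ex) == 0:
        raise ValidationError("no scored validation epochs")

    present = {int(train_recs[r].labels[k - 1]) for r, k in train_ex}
    missing = [AASM_STAGES[i] for i in range(len(AASM_STAGES)) if i not in present]
    if missing:
        logger.warning("stages absent from training data: %s", ", ".join(missing))

    ss = np.random.SeedSequence(seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    model.reseed_dropout(int(ss.generate_state(1)[0]) % (2**31))

    def val_loss() -> float:
        tot, n = 0.0, 0
        for st in range(0, len(val_ex), s.batch_size):
            batch = val_ex[st : st + s.batch_size]
            tot += model.batch_loss(val_recs, batch, train=False) * len(batch)
            n += len(batch)
        return tot / n

    # The batch size is capped at 100 patterns; on small training sets it
    # shrinks so that one epoch still holds (at least) the 5 evaluation
    # points and the patience of 10 evaluations still equals two passes
    # over the training data.
    batch_size = min(s.batch_size, max(1, math.ceil(len(train_ex) / s.evals_per_epoch)))

    state = TrainState()
    best_snapshot = model.snapshot()
    params = model.parameters()
    step = 0
    for epoch in range(1, s.max_epochs + 1):
        state.epoch = epoch
        lr = lr_at(epoch, s.initial_lr, s.min_lr)
        perm = shuffle_rng.permutation(len(train_ex))
        batches = [
            train_ex[perm[st : st + batch_size]]
            for st in range(0, len(train_ex), batch_size)
        ]
        nb = len(batches)
        eval_points = sorted({math.ceil(j * nb / s.evals_per_epoch) for j in
                              range(1, s.evals_per_epoch + 1)})
        for bi, batch in enumerate(batches, start=1):
            tr_loss = model.batch_loss(train_recs, batch, train=True)
            for p, g in params:
                p -= (lr * g).astype(p.dtype)
            step += 1
            if bi in eval_points:
                vl = val_loss()
                state.n_evals += 1
                state.history.append((step, tr_loss, vl))
                if vl < state.best_val_loss - s.improve_tol:
                    state.best_val_loss = vl
                    state.best_eval = state.n_evals
                    state.evals_since_improve = 0
                    best_snapshot = model.snapshot()
                else:
                    state.evals_since_improve += 1
                    if state.evals_since_improve >= s.patience:
                        state.stopped_early = True
                        model.restore(best_snapshot)
                        logger.info(
                            "early stop at epoch %d (eval %d, best %.5f)",
                            epoch, state.n_evals, state.best_val_loss,
                        )
                        return state
    model.restore(best_snapshot)
    return state


def weight_checksum(model: SleepStager) -> str:
    """Stable hex digest of all weights (for determinism audits)."""
    import hashlib

    h = hashlib.sha256()
    for p, _ in model.parameters():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()
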