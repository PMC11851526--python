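"""Frame-wise action-unit models on flattened 3D landmarks.

Both models are the same lightweight fully-connected network — input
3·Ns, one hidden layer of 128 ReLU units — differing only in the head:

* detector: 8 logistic outputs (one per AU) trained with per-unit binary
  cross-entropy, the standard multi-label treatment;
* intensity estimator: 5 linear outputs trained with mean squared error,
  matching RMSE-based evaluation; predictions are reported after clamping
  to the FACS 0-5 scale.

Training is mini-batch Adam (betas 0.9/0.999) with seeded shuffling, so a
fixed seed reproduces the loss trajectory exactly on one platform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .exceptions import ContractViolationError, InvalidInputError
from .landmarks import (
    INTENSITY_AU_IDS,
    LandmarkFrame,
    Segment,
    flatten_frame,
    normalize_frame,
)


@dataclass
class AUDetectorConfig:
    """Architecture and optimizer settings for the frame-wise AU network."""

    input_size: int = 3 * 478
    hidden_units: int = 128
    output_units: int = 8
    batch_size: int = 64
    max_epochs: int = 500
    learning_rate: float = 0.01
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    threshold: float = 0.5
    patience: int | None = None  # early stopping off by default
    seed: int = 0

    def __post_init__(self):
        if min(self.input_size, self.hidden_units, self.output_units,
               self.batch_size, self.max_epochs) <= 0:
            raise InvalidInputError("sizes and epochs must be positive")
        if not (0 < self.learning_rate < 1 and 0 < self.adam_beta1 < 1
                and 0 < self.adam_beta2 < 1):
            raise InvalidInputError("rates must lie in (0, 1)")


@dataclass
class AUVector:
    """Per-frame AU presence probabilities and optional binarization."""

    scores: np.ndarray  # (8,) in [0, 1]
    binarized: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise InvalidInputError("scores must lie in [0, 1]")


class _TwoLayerNet:
    """Dense(3·Ns→128) + ReLU + Dense(128→out), shared by both heads."""

    def __init__(self, config: AUDetectorConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFC]))
        self.fc1 = nn.Dense(config.input_size, config.hidden_units, rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Dense(config.hidden_units, config.output_units, rng)
        self.unreliable_outputs: list[int] = []
        self.history: list[float] = []

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.relu.forward(self.fc1.forward(X)))

    def backward(self, dlogits: np.ndarray) -> None:
        self.fc1.backward(self.relu.backward(self.fc2.backward(dlogits)))

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arch = asdict(self.config)
        arch["kind"] = type(self).__name__
        path.with_suffix(".json").write_text(json.dumps(arch, indent=2))
        np.savez(path.with_suffix(".npz"),
                 W1=self.fc1.W.value, b1=self.fc1.b.value,
                 W2=self.fc2.W.value, b2=self.fc2.b.value)

    @classmethod
    def load(cls, path: str | Path) -> "_TwoLayerNet":
        path = Path(path)
        arch = json.loads(path.with_suffix(".json").read_text())
        arch.pop("kind", None)
        model = cls(AUDetectorConfig(**arch))
        data = np.load(path.with_suffix(".npz"))
        model.fc1.W.value = data["W1"]
        model.fc1.b.value = data["b1"]
        model.fc2.W.value = data["W2"]
        model.fc2.b.value = data["b2"]
        return model


class AUDetectorModel(_TwoLayerNet):
    """Multi-label AU presence detector; scores via per-unit logistic."""

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.logits(np.asarray(X, dtype=np.float64)))


class IntensityModel(_TwoLayerNet):
    """AU intensity regressor with a linear head; reports clamp to [0, 5]."""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.logits(np.asarray(X, dtype=np.float64)), 0.0, 5.0)


def _train(model: _TwoLayerNet, X: np.ndarray, Y: np.ndarray, loss_fn,
           log_path: str | Path | None = None) -> _TwoLayerNet:
    cfg = model.config
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("X and Y row counts differ")
    if X.shape[1] != cfg.input_size:
        raise InvalidInputError(
            f"model expects input_size {cfg.input_size}, got {X.shape[1]}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5F]))
    opt = nn.Adam(model.params(), lr=cfg.learning_rate,
                  beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    n = X.shape[0]
    best = np.inf
    stale = 0
    rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            logits = model.logits(X[idx])
            loss, dlogits = loss_fn(logits, Y[idx])
            model.backward(dlogits)
            opt.step()
            total += loss * len(idx)
        epoch_loss = total / n
        model.history.append(epoch_loss)
        rows.append((epoch, epoch_loss))
        if cfg.patience is not None:
            if epoch_loss < best - 1e-9:
                best, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("epoch,loss\n")
            for e, l in rows:
                fh.write(f"{e},{l:.8f}\n")
    return model


def train_au_detector(X: np.ndarray, Y: np.ndarray, config: AUDetectorConfig,
                      log_path: str | Path | None = None) -> AUDetectorModel:
    """Train the 8-output presence detector on flattened, normalized frames.

    ``X`` is (n, 3·Ns), ``Y`` is (n, 8) binary. An AU column with no
    positives (or no negatives) is trained anyway but flagged in
    ``model.unreliable_outputs`` with a warning.
    """
    Y = np.asarray(Y)
    model = AUDetectorModel(config)
    for j in range(Y.shape[1]):
        npos = int(Y[:, j].sum())
        if npos == 0 or npos == Y.shape[0]:
            warnings.warn(
                f"AU output {j} has {'no positive' if npos == 0 else 'no negative'} "
                "training frames; its scores are unreliable", stacklevel=2)
            model.unreliable_outputs.append(j)
    return _train(model, X, Y, nn.bce_with_logits, log_path)


def predict_au(model: AUDetectorModel, frame_or_X, threshold: float | None = None):
    """Scores (and binarization) for one frame or a batch of flat vectors."""
    if isinstance(frame_or_X, LandmarkFrame):
        X = flatten_frame(frame_or_X)[None, :]
        single = True
    else:
        X = np.atleast_2d(np.asarray(frame_or_X, dtype=np.float64))
        single = X.shape[0] == 1 and np.asarray(frame_or_X).ndim == 1
    if X.shape[1] != model.config.input_size:
        raise InvalidInputError(
            f"expected {model.config.input_size} inputs, got {X.shape[1]}")
    scores = model.predict_scores(X)
    thr = model.config.threshold if threshold is None else threshold
    if single:
        return AUVector(scores[0], binarize(scores[0], thr))
    return scores


def binarize(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Elementwise presence decision: score >= threshold."""
    return (np.asarray(scores) >= threshold).astype(np.int8)


def train_intensity_estimator(X: np.ndarray, Y: np.ndarray,
                              config: AUDetectorConfig | None = None,
                              log_path: str | Path | None = None) -> IntensityModel:
    """Train the 5-output linear-head intensity regressor (MSE loss)."""
    if config is None:
        config = AUDetectorConfig(output_units=5)
    if config.output_units != len(INTENSITY_AU_IDS):
        raise InvalidInputError("intensity estimator needs output_units=5")
    Y = np.asarray(Y, dtype=np.float64)
    if Y.size == 0:
        raise ContractViolationError("no intensity-labeled frames provided")
    return _train(IntensityModel(config), X, Y, nn.mse_loss, log_path)


def predict_intensity(model: IntensityModel, frame_or_X) -> np.ndarray:
    """Clamped [0, 5] intensity predictions for a frame or batch."""
    if isinstance(frame_or_X, LandmarkFrame):
        return model.predict(flatten_frame(frame_or_X)[None, :])[0]
    return model.predict(np.atleast_2d(np.asarray(frame_or_X, dtype=np.float64)))


def round_intensity(values: np.ndarray) -> np.ndarray:
    """Nearest integer in {0..5}; ties round half away from zero."""
    v = np.asarray(values, dtype=np.float64)
    rounded = np.sign(v) * np.floor(np.abs(v) + 0.5)
    return np.clip(rounded, 0, 5).astype(np.int64)


def collect_frames(segments: list[Segment], template: LandmarkFrame,
                   stride: int = 1, normalize: bool = True):
    """Assemble a frame-level training table from segments.

    Returns ``(X, Y_presence, Y_intensity, subject_ids)`` where ``X`` holds
    flattened (optionally Procrustes-normalized) frames sampled every
    ``stride`` frames; ``Y_intensity`` is None if any segment lacks
    intensity labels.
    """
    Xs, Yp, Yi, subs = [], [], [], []
    any_unlabeled = any(seg.au_intensity is None for seg in segments)
    for seg in segments:
        seq = seg.sequence
        for t in range(0, seq.n_frames, stride):
            fr = seq.frame(t)
            if normalize:
                fr = normalize_frame(fr, template)
            Xs.append(flatten_frame(fr))
            Yp.append(seg.au_presence[t])
            if not any_unlabeled:
                Yi.append(seg.au_intensity[t])
            subs.append(seq.subject_id)
    X = np.asarray(Xs)
    return (X, np.asarray(Yp),
            None if any_unlabeled else np.asarray(Yi), np.asarray(subs))
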