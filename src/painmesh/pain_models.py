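"""Temporal pain classification over action-unit time series.

Two classifiers consume fixed-length windows of per-frame AU vectors
(8 predicted or ground-truth presences, or all 34 ground-truth AUs):

* a Transformer encoder — linear projection of each AU vector, summed
  with fixed sinusoidal positional encodings, passed through stacked
  self-attention blocks; the representation of the last non-padded frame
  feeds a small MLP with a logistic output;
* a two-layer LSTM baseline whose hidden state at the last non-padded
  frame feeds the same kind of head.

The exposed contract is a pain probability in [0, 1]; the hard label is
its round (decision threshold 0.5). Class convention: pain = 1, other = 0.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .exceptions import ContractViolationError, InvalidInputError


@dataclass
class AUSequenceWindow:
    """A fixed-length window of AU vectors with a validity mask."""

    values: np.ndarray  # (T, Na)
    mask: np.ndarray    # (T,) True where the frame is real (not padding)
    label: int          # pain = 1, other = 0
    subject_id: str = ""
    segment_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.mask.shape != (self.values.shape[0],):
            raise InvalidInputError("values must be (T, Na) with a length-T mask")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("window values must be finite")
        if not self.mask.any():
            raise InvalidInputError("window must contain at least one real frame")


@dataclass
class PainTransformerConfig:
    projection_dim: int = 1024
    num_heads: int = 4
    num_encoder_layers: int = 2
    ffn_dim: int | None = None  # default: 2 × projection_dim
    mlp_hidden: int = 256
    dropout: float = 0.1
    learning_rate: float = 1e-5
    batch_size: int = 16
    max_epochs: int = 150
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    seed: int = 0

    def __post_init__(self):
        if self.projection_dim % self.num_heads != 0:
            raise InvalidInputError("projection_dim must be divisible by num_heads")
        if self.ffn_dim is None:
            self.ffn_dim = 2 * self.projection_dim


@dataclass
class PainLSTMConfig:
    num_layers: int = 2
    hidden_dim: int = 512
    mlp_hidden: int = 256
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 150
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    seed: int = 0

    def __post_init__(self):
        if min(self.num_layers, self.hidden_dim, self.batch_size,
               self.max_epochs) <= 0:
            raise InvalidInputError("sizes must be positive")


def window_segments(au_sequences, T: int = 350, stride: int | None = None,
                    min_tail_fraction: float = 0.5,
                    min_length: int = 10) -> list[AUSequenceWindow]:
    """Cut labelled AU sequences into fixed-length windows.

    ``au_sequences`` is an iterable of ``(values (L, Na), label, subject_id,
    segment_id)``. Default stride is T (non-overlapping); if the uncovered
    tail is at least ``min_tail_fraction * T`` one extra right-aligned
    window is added. Sequences shorter than T yield one right-zero-padded
    window with a padding mask; sequences shorter than ``min_length`` are
    skipped with a warning. Windows inherit the sequence's label and
    subject.
    """
    if stride is None:
        stride = T
    out: list[AUSequenceWindow] = []
    for values, label, subject_id, segment_id in au_sequences:
        values = np.asarray(values, dtype=np.float64)
        L = values.shape[0]
        if L < min_length:
            warnings.warn(f"segment {segment_id!r} has only {L} frames; skipped",
                          stacklevel=2)
            continue
        if L < T:
            padded = np.zeros((T, values.shape[1]))
            padded[:L] = values
            mask = np.zeros(T, dtype=bool)
            mask[:L] = True
            out.append(AUSequenceWindow(padded, mask, label, subject_id, segment_id))
            continue
        starts = list(range(0, L - T + 1, stride))
        covered_end = starts[-1] + T
        if L - covered_end >= min_tail_fraction * T:
            starts.append(L - T)
        for s in starts:
            out.append(AUSequenceWindow(values[s:s + T], np.ones(T, dtype=bool),
                                        label, subject_id, segment_id))
    return out


class _HeadMLP:
    """Dense -> ReLU -> Dropout -> Dense(1): logistic pain head."""

    def __init__(self, d_in: int, hidden: int, dropout: float,
                 rng: np.random.Generator):
        self.fc1 = nn.Dense(d_in, hidden, rng)
        self.relu = nn.ReLU()
        self.drop = nn.Dropout(dropout, rng)
        self.fc2 = nn.Dense(hidden, 1, rng)

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, z: np.ndarray, train: bool) -> np.ndarray:
        return self.fc2.forward(
            self.drop.forward(self.relu.forward(self.fc1.forward(z)), train))[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.relu.backward(self.drop.backward(
            self.fc2.backward(dlogit[:, None]))))


def _stack_windows(windows):
    V = np.stack([w.values for w in windows])
    M = np.stack([w.mask for w in windows])
    y = np.array([w.label for w in windows], dtype=np.float64)
    return V, M, y


class PainTransformerModel:
    """Transformer-encoder pain classifier (see module docstring)."""

    def __init__(self, n_aus: int, config: PainTransformerConfig):
        self.n_aus = n_aus
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7E]))
        d = config.projection_dim
        self.proj = nn.Dense(n_aus, d, rng)
        self.layers = [
            nn.TransformerEncoderLayer(d, config.num_heads, config.ffn_dim,
                                       rng, config.dropout)
            for _ in range(config.num_encoder_layers)
        ]
        self.head = _HeadMLP(d, config.mlp_hidden, config.dropout, rng)
        self.history: list[float] = []
        self._pe_cache: dict[int, np.ndarray] = {}

    def params(self):
        ps = self.proj.params()
        for layer in self.layers:
            ps += layer.params()
        return ps + self.head.params()

    def encode(self, V: np.ndarray, M: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, T, Na) AU windows -> (B, T, d) representations."""
        B, T, na = V.shape
        if na != self.n_aus:
            raise InvalidInputError(
                f"model trained on {self.n_aus} AUs, got {na}")
        pe = self._pe_cache.setdefault(
            T, nn.sinusoidal_positional_encoding(T, self.config.projection_dim))
        z = self.proj.forward(V) + pe
        for layer in self.layers:
            z = layer.forward(z, key_mask=M, train=train)
        return z

    def _forward_logits(self, V, M, train):
        z = self.encode(V, M, train)
        last = M.shape[1] - 1 - np.argmax(M[:, ::-1], axis=1)  # last valid index
        self._last_idx = last
        self._z_shape = z.shape
        zlast = z[np.arange(z.shape[0]), last]
        return self.head.forward(zlast, train)

    def _backward(self, dlogit):
        dzlast = self.head.backward(dlogit)
        dz = np.zeros(self._z_shape)
        dz[np.arange(dz.shape[0]), self._last_idx] = dzlast
        for layer in reversed(self.layers):
            dz = layer.backward(dz)
        self.proj.backward(dz)

    def predict_proba(self, windows) -> np.ndarray:
        V, M, _ = _stack_windows(windows)
        return nn.sigmoid(self._forward_logits(V, M, train=False))


class PainLSTMModel:
    """Stacked-LSTM pain classifier baseline."""

    def __init__(self, n_aus: int, config: PainLSTMConfig):
        self.n_aus = n_aus
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x15]))
        self.lstms = []
        d_in = n_aus
        for _ in range(config.num_layers):
            self.lstms.append(nn.LSTMLayer(d_in, config.hidden_dim, rng))
            d_in = config.hidden_dim
        self.head = _HeadMLP(config.hidden_dim, config.mlp_hidden, 0.0, rng)
        self.history: list[float] = []

    def params(self):
        ps = []
        for l in self.lstms:
            ps += l.params()
        return ps + self.head.params()

    def _forward_logits(self, V, M, train):
        if V.shape[2] != self.n_aus:
            raise InvalidInputError(
                f"model trained on {self.n_aus} AUs, got {V.shape[2]}")
        h = V
        for l in self.lstms:
            h = l.forward(h)
        last = M.shape[1] - 1 - np.argmax(M[:, ::-1], axis=1)
        self._last_idx = last
        self._h_shape = h.shape
        hlast = h[np.arange(h.shape[0]), last]
        return self.head.forward(hlast, train)

    def _backward(self, dlogit):
        dhlast = self.head.backward(dlogit)
        dh = np.zeros(self._h_shape)
        dh[np.arange(dh.shape[0]), self._last_idx] = dhlast
        for l in reversed(self.lstms):
            dh = l.backward(dh)

    def predict_proba(self, windows) -> np.ndarray:
        V, M, _ = _stack_windows(windows)
        return nn.sigmoid(self._forward_logits(V, M, train=False))


def train_pain_model(windows: list[AUSequenceWindow],
                     config: PainTransformerConfig | PainLSTMConfig):
    """Train a pain classifier on training-split windows.

    Refuses a single-class training set. Mini-batch Adam with seeded
    shuffling; binary cross-entropy on the logistic output.
    """
    labels = {w.label for w in windows}
    if labels != {0, 1}:
        raise ContractViolationError(
            f"training windows must contain both classes, got labels {sorted(labels)}")
    n_aus = windows[0].values.shape[1]
    if isinstance(config, PainTransformerConfig):
        model = PainTransformerModel(n_aus, config)
    elif isinstance(config, PainLSTMConfig):
        model = PainLSTMModel(n_aus, config)
    else:
        raise InvalidInputError(f"unknown config type {type(config).__name__}")
    V, M, y = _stack_windows(windows)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A]))
    opt = nn.Adam(model.params(), lr=config.learning_rate,
                  beta1=config.adam_beta1, beta2=config.adam_beta2)
    n = len(windows)
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = model._forward_logits(V[idx], M[idx], train=True)
            loss, dlogit = nn.bce_with_logits(logits, y[idx])
            model._backward(dlogit)
            opt.step()
            total += loss * len(idx)
        model.history.append(total / n)
    return model


def save_pain_model(model, path: str | Path) -> None:
    """Checkpoint a pain model: architecture JSON + weight arrays."""
    path = Path(path)
    arch = asdict(model.config)
    arch["kind"] = type(model).__name__
    arch["n_aus"] = model.n_aus
    path.with_suffix(".json").write_text(json.dumps(arch, indent=2))
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path.with_suffix(".npz"), **arrays)


def load_pain_model(path: str | Path):
    path = Path(path)
    arch = json.loads(path.with_suffix(".json").read_text())
    kind = arch.pop("kind")
    n_aus = arch.pop("n_aus")
    if kind == "PainTransformerModel":
        model = PainTransformerModel(n_aus, PainTransformerConfig(**arch))
    elif kind == "PainLSTMModel":
        model = PainLSTMModel(n_aus, PainLSTMConfig(**arch))
    else:
        raise InvalidInputError(f"unknown checkpoint kind {kind!r}")
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    return model


def export_predictions_csv(windows, probabilities, path: str | Path) -> None:
    """Write per-window predictions as segment_id,subject_id,probability,label."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["segment_id", "subject_id", "probability", "label"])
        for w, p in zip(windows, probabilities):
            writer.writerow([w.segment_id, w.subject_id, f"{p:.6f}",
                             pain_label(float(p))])


def predict_pain(model, window: AUSequenceWindow) -> float:
    """Pain probability for one window."""
    return float(model.predict_proba([window])[0])


def pain_label(probability: float) -> int:
    """Hard decision: round(probability), i.e. 1 iff probability >= 0.5."""
    return int(probability >= 0.5)


def segment_decision(window_labels) -> int:
    """Segment-level decision: majority vote over its windows, ties -> pain."""
    window_labels = list(window_labels)
    if not window_labels:
        raise InvalidInputError("segment has no windows")
    votes = sum(window_labels)
    return int(votes * 2 >= len(window_labels))


def encode_sequence(model: PainTransformerModel, window: AUSequenceWindow) -> np.ndarray:
    """The (T, d) Transformer representation of one window."""
    return model.encode(window.values[None], window.mask[None])[0]
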