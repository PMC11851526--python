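"""Subject-independent evaluation protocols and metrics.

Cross-validation is always partitioned by subject: no person contributes
frames to both the train and test side of any fold. AU detection is scored
with per-AU F1 (macro-averaged over folds, then unweighted-averaged over
AUs), intensity estimation with RMSE/MAE, and pain classification with
per-fold accuracy/F1 plus a confusion matrix summed over folds.
Percentages in rendered tables are given to 2 decimals, half-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .au_models import (
    AUDetectorConfig,
    collect_frames,
    train_au_detector,
    train_intensity_estimator,
)
from .augmentation import AugmentationSpec, oversample_rare
from .exceptions import InvalidInputError
from .landmarks import (
    DETECTION_AU_IDS,
    INTENSITY_AU_IDS,
    LandmarkFrame,
    Segment,
)
from .pain_models import (
    PainLSTMConfig,
    PainTransformerConfig,
    segment_decision,
    train_pain_model,
    window_segments,
)


@dataclass
class FoldAssignment:
    """Balanced random partition of subjects into k folds."""

    k: int
    mapping: dict[str, int]
    seed: int = 0

    def __post_init__(self):
        sizes = self.fold_sizes()
        if max(sizes) - min(sizes) > 1:
            raise InvalidInputError("fold sizes must differ by at most 1")

    def fold_sizes(self) -> list[int]:
        return [sum(1 for f in self.mapping.values() if f == i)
                for i in range(self.k)]

    def test_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.mapping.items() if f == fold}

    def train_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.mapping.items() if f != fold}


def assign_folds(subject_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Deterministic balanced subject partition for k-fold CV."""
    subjects = list(dict.fromkeys(subject_ids))
    if k > len(subjects):
        raise InvalidInputError(
            f"cannot make {k} folds from {len(subjects)} subjects")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF01D]))
    order = rng.permutation(len(subjects))
    mapping = {subjects[j]: i % k for i, j in enumerate(order)}
    return FoldAssignment(k=k, mapping=mapping, seed=seed)


@dataclass
class ConfusionMatrix2x2:
    """Binary confusion counts; positive class = pain."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise InvalidInputError("counts must be nonnegative")

    def __add__(self, other: "ConfusionMatrix2x2") -> "ConfusionMatrix2x2":
        return ConfusionMatrix2x2(self.tn + other.tn, self.fp + other.fp,
                                  self.fn + other.fn, self.tp + other.tp)

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def as_dict(self) -> dict:
        return {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp}


def f1_precision_recall(y_true, y_pred, positive_label=1,
                        empty_value: float = 0.0):
    """(f1, precision, recall) with empty denominators mapped to
    ``empty_value`` (0 by default; pass nan to mark them undefined)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("y_true and y_pred lengths differ")
    tp = int(np.sum((y_true == positive_label) & (y_pred == positive_label)))
    fp = int(np.sum((y_true != positive_label) & (y_pred == positive_label)))
    fn = int(np.sum((y_true == positive_label) & (y_pred != positive_label)))
    precision = tp / (tp + fp) if tp + fp else empty_value
    recall = tp / (tp + fn) if tp + fn else empty_value
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else empty_value)
    return f1, precision, recall


def rmse_mae(y_true, y_pred):
    """Root-mean-square error and mean absolute error."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.size == 0:
        raise InvalidInputError("empty input")
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("y_true and y_pred shapes differ")
    diff = y_pred - y_true
    return float(np.sqrt(np.mean(diff ** 2))), float(np.mean(np.abs(diff)))


def matrix_metrics(cm: ConfusionMatrix2x2) -> dict:
    """Accuracy, precision, recall and F1 from binary confusion counts."""
    if cm.total == 0:
        raise InvalidInputError("confusion matrix is empty")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"accuracy": accuracy, "precision": precision,
            "recall": recall, "f1": f1}


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (table convention)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass
class EvalReport:
    """Evaluation results with self-consistency checks on emit."""

    kind: str  # au_detection / au_intensity / pain
    per_au: pd.DataFrame | None = None
    fold_metrics: pd.DataFrame | None = None
    confusion: ConfusionMatrix2x2 | None = None
    extras: dict = field(default_factory=dict)

    def consistency_check(self, atol: float = 0.005) -> None:
        """Every emitted AVG must equal the mean of its row's cells."""
        if self.per_au is not None and "AVG" in self.per_au.columns:
            cells = self.per_au.drop(columns="AVG")
            avg = cells.mean(axis=1)
            if not np.allclose(avg, self.per_au["AVG"], atol=atol):
                raise AssertionError("AVG column inconsistent with row cells")
        if self.confusion is not None and self.fold_metrics is not None:
            agg = matrix_metrics(self.confusion)
            if "aggregate_accuracy" in self.extras:
                if abs(agg["accuracy"] - self.extras["aggregate_accuracy"]) > 1e-9:
                    raise AssertionError("aggregate accuracy inconsistent")

    def to_json(self) -> str:
        obj = {"kind": self.kind, "extras": self.extras}
        if self.per_au is not None:
            obj["per_au"] = json.loads(self.per_au.to_json(orient="index"))
        if self.fold_metrics is not None:
            obj["fold_metrics"] = json.loads(self.fold_metrics.to_json(orient="index"))
        if self.confusion is not None:
            obj["confusion"] = self.confusion.as_dict()
        return json.dumps(obj, indent=2)

    def save(self, directory: str | Path, stem: str) -> None:
        self.consistency_check()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / f"{stem}.json").write_text(self.to_json())
        if self.per_au is not None:
            self.per_au.to_csv(directory / f"{stem}_per_au.csv")
        if self.fold_metrics is not None:
            self.fold_metrics.to_csv(directory / f"{stem}_folds.csv")

    def render_text(self) -> str:
        lines = [f"[{self.kind}]"]
        if self.per_au is not None:
            lines.append(self.per_au.round(2).to_string())
        if self.fold_metrics is not None:
            lines.append(self.fold_metrics.round(4).to_string())
        if self.confusion is not None:
            cm = self.confusion
            lines.append("Summed confusion matrix (rows: true, cols: predicted)")
            lines.append(f"          Others   Pain")
            lines.append(f"  Others  {cm.tn:6d} {cm.fp:6d}")
            lines.append(f"  Pain    {cm.fn:6d} {cm.tp:6d}")
            m = matrix_metrics(cm)
            lines.append(
                "  accuracy {:.2f}%  F1 {:.2f}%".format(
                    round_half_up(100 * m['accuracy']),
                    round_half_up(100 * m['f1'])))
        for k, v in self.extras.items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines)


def _split_segments(segments, subjects: set[str]):
    return [s for s in segments if s.sequence.subject_id in subjects]


def run_au_cv(segments: list[Segment], template: LandmarkFrame, k: int = 3,
              config: AUDetectorConfig | None = None,
              augmentation_spec: AugmentationSpec | None = None,
              oversample_target_indices: list[int] | None = None,
              copies_per_positive: int = 4, mirror=None,
              frame_stride: int = 1, seed: int = 0,
              threshold: float = 0.5) -> EvalReport:
    """Subject-independent k-fold CV of the AU presence detector.

    Per fold: train on ~ (k-1)/k of subjects (optionally with rare-AU
    oversampling of the training split), score per-AU F1 on the held-out
    subjects. The report gives per-AU means across folds plus their
    unweighted average (AVG).
    """
    if config is None:
        config = AUDetectorConfig(input_size=3 * template.n_points)
    folds = assign_folds([s.sequence.subject_id for s in segments], k, seed)
    n_aus = len(DETECTION_AU_IDS)
    per_fold_f1 = np.zeros((k, n_aus))
    for fold in range(k):
        train_subj = folds.train_subjects(fold)
        test_subj = folds.test_subjects(fold)
        assert not (train_subj & test_subj), "fold leaks subjects"
        train_segs = _split_segments(segments, train_subj)
        if augmentation_spec is not None and oversample_target_indices:
            train_segs = oversample_rare(
                train_segs, "train", oversample_target_indices,
                copies_per_positive, augmentation_spec, mirror)
        Xtr, Ytr, _, _ = collect_frames(train_segs, template, frame_stride)
        Xte, Yte, _, _ = collect_frames(
            _split_segments(segments, test_subj), template, frame_stride)
        model = train_au_detector(Xtr, Ytr, config)
        pred = (model.predict_scores(Xte) >= threshold).astype(np.int8)
        for j in range(n_aus):
            per_fold_f1[fold, j] = f1_precision_recall(Yte[:, j], pred[:, j])[0]
    per_au = per_fold_f1.mean(axis=0)
    cols = [f"AU{a}" for a in DETECTION_AU_IDS]
    df = pd.DataFrame([list(100 * per_au) + [100 * per_au.mean()]],
                      columns=cols + ["AVG"], index=["FCN"])
    folds_df = pd.DataFrame(100 * per_fold_f1, columns=cols)
    folds_df.index.name = "fold"
    return EvalReport(kind="au_detection", per_au=df, fold_metrics=folds_df,
                      extras={"macro_f1": float(per_au.mean())})


def run_intensity_cv(segments: list[Segment], template: LandmarkFrame,
                     k: int = 3, config: AUDetectorConfig | None = None,
                     frame_stride: int = 1, seed: int = 0) -> EvalReport:
    """Subject-independent k-fold CV of the intensity estimator
    (per-AU RMSE and MAE, averaged over folds, plus unweighted AVG)."""
    if config is None:
        config = AUDetectorConfig(input_size=3 * template.n_points, output_units=5)
    folds = assign_folds([s.sequence.subject_id for s in segments], k, seed)
    n_aus = len(INTENSITY_AU_IDS)
    rmse_f = np.zeros((k, n_aus))
    mae_f = np.zeros((k, n_aus))
    for fold in range(k):
        Xtr, _, Itr, _ = collect_frames(
            _split_segments(segments, folds.train_subjects(fold)),
            template, frame_stride)
        Xte, _, Ite, _ = collect_frames(
            _split_segments(segments, folds.test_subjects(fold)),
            template, frame_stride)
        if Itr is None or Ite is None:
            raise InvalidInputError("intensity CV needs intensity-labeled segments")
        model = train_intensity_estimator(Xtr, Itr, config)
        pred = model.predict(Xte)
        for j in range(n_aus):
            rmse_f[fold, j], mae_f[fold, j] = rmse_mae(Ite[:, j], pred[:, j])
    cols = [f"AU{a}" for a in INTENSITY_AU_IDS]
    rows = []
    for name, arr in (("RMSE", rmse_f), ("MAE", mae_f)):
        m = arr.mean(axis=0)
        rows.append(pd.Series(list(m) + [m.mean()], index=cols + ["AVG"], name=name))
    df = pd.DataFrame(rows)
    return EvalReport(kind="au_intensity", per_au=df,
                      extras={"avg_rmse": float(rmse_f.mean()),
                              "avg_mae": float(mae_f.mean())})


def _au_sequences_for(segments: list[Segment], au_source: str,
                      template: LandmarkFrame | None = None,
                      detector=None, frame_stride: int = 1):
    """Per-segment AU time series for the chosen input setting.

    ``predicted8``: detector scores per frame (Algorithm: landmark frame ->
    AU vector); ``ground8``: the 8 ground-truth presences; ``groundAll``:
    all simulated ground-truth AU presences.
    """
    seqs = []
    for seg in segments:
        label = 1 if seg.sequence.segment_class == "pain" else 0
        if au_source == "ground8":
            values = seg.au_presence[::frame_stride].astype(np.float64)
        elif au_source == "groundAll":
            full = getattr(seg, "au_full", None)
            if full is None:
                raise InvalidInputError(
                    "groundAll requires segments carrying the full AU matrix")
            values = full[::frame_stride].astype(np.float64)
        elif au_source == "predicted8":
            if detector is None or template is None:
                raise InvalidInputError(
                    "predicted8 requires a trained AU detector and template")
            X, _, _, _ = collect_frames([seg], template, frame_stride)
            values = detector.predict_scores(X)
        else:
            raise InvalidInputError(f"unknown au_source {au_source!r}")
        seqs.append((values, label, seg.sequence.subject_id,
                     seg.sequence.segment_id))
    return seqs


def run_pain_cv(segments: list[Segment],
                model_config: PainTransformerConfig | PainLSTMConfig,
                k: int = 10, au_source: str = "ground8",
                template: LandmarkFrame | None = None,
                detector_config: AUDetectorConfig | None = None,
                window_length: int = 350, window_stride: int | None = None,
                frame_stride: int = 1, seed: int = 0) -> EvalReport:
    """Subject-independent k-fold CV of pain classification.

    In ``predicted8`` mode an AU detector is trained per fold on that
    fold's training subjects, so the AU inputs of held-out subjects come
    from a detector that never saw them. Segment-level decisions are a
    majority vote over the segment's windows (ties -> pain); accuracy/F1
    are reported per fold and the confusion matrix is summed over folds.
    """
    folds = assign_folds([s.sequence.subject_id for s in segments], k, seed)
    total_cm = ConfusionMatrix2x2(0, 0, 0, 0)
    rows = []
    for fold in range(k):
        train_subj = folds.train_subjects(fold)
        test_subj = folds.test_subjects(fold)
        assert not (train_subj & test_subj), "fold leaks subjects"
        train_segs = _split_segments(segments, train_subj)
        test_segs = _split_segments(segments, test_subj)
        detector = None
        if au_source == "predicted8":
            if template is None:
                raise InvalidInputError("predicted8 requires the template")
            cfg = detector_config or AUDetectorConfig(
                input_size=3 * template.n_points)
            Xtr, Ytr, _, _ = collect_frames(train_segs, template, frame_stride)
            detector = train_au_detector(Xtr, Ytr, cfg)
        train_windows = window_segments(
            _au_sequences_for(train_segs, au_source, template, detector,
                              frame_stride),
            T=window_length, stride=window_stride)
        test_windows = window_segments(
            _au_sequences_for(test_segs, au_source, template, detector,
                              frame_stride),
            T=window_length, stride=window_stride)
        model = train_pain_model(train_windows, model_config)
        probs = model.predict_proba(test_windows)
        # aggregate window votes per segment
        by_segment: dict[str, list[int]] = {}
        seg_label: dict[str, int] = {}
        for w, p in zip(test_windows, probs):
            by_segment.setdefault(w.segment_id, []).append(int(p >= 0.5))
            seg_label[w.segment_id] = w.label
        y_true, y_pred = [], []
        for sid, votes in by_segment.items():
            y_true.append(seg_label[sid])
            y_pred.append(segment_decision(votes))
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        cm = ConfusionMatrix2x2(
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tp=int(np.sum((y_true == 1) & (y_pred == 1))))
        total_cm = total_cm + cm
        m = matrix_metrics(cm)
        rows.append({"fold": fold, "accuracy": m["accuracy"], "f1": m["f1"],
                     **cm.as_dict()})
    folds_df = pd.DataFrame(rows).set_index("fold")
    agg = matrix_metrics(total_cm)
    return EvalReport(
        kind="pain", fold_metrics=folds_df, confusion=total_cm,
        extras={"aggregate_accuracy": agg["accuracy"],
                "aggregate_f1": agg["f1"], "au_source": au_source,
                "model": type(model_config).__name__})
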