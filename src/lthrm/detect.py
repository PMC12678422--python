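"""Rolling-window classifier detection of swallow starts.

Training windows are 36 x 500 slices of the preprocessed (0-255) matrix:
one positive per annotated swallow start, with the upper-esophageal-
sphincter relaxation at the left edge of the window, and negatives tiled
non-overlapping inside inter-swallow gaps shrunk by a guard margin (so that
tails of neighboring swallows cannot leak in).  Classes are balanced by
seeded subsampling of the majority class.

At inference a window slides over the recording; per window the classifier
emits the predicted class o_i and its confidence c_i (the predicted-class
probability).  The trace s = o * c keeps only class-1 confidences; it is
smoothed with a moving average (w = 20), thresholded at 0.2, and every
maximal run of ones becomes one detection whose predicted start is the
(first) argmax of the raw trace s inside the run's span.

The shipped backbone ("tiny") is a small multi-layer perceptron trained
from scratch by stochastic gradient descent (learning rate 3e-3, batch
size 128, 20 epochs) on windows bilinearly downsampled to 36 x 50 and
scaled to [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .io import AnnotationSet, DetectionResult, PreprocessedRecording
from .preprocess import moving_average, resize_windows

logger = logging.getLogger(__name__)

WINDOW = 500
GUARD_MARGIN = 250

BACKBONES: dict[str, dict] = {
    # input shape keeps all 36 sensor rows; time axis downsampled 10x
    "tiny": {"input_shape": (36, 50), "hidden_layer_sizes": (64,)},
}


@dataclass
class SwallowWindow:
    """One 36 x 500 window on the preprocessed scale with a binary label."""

    values: np.ndarray
    label: int
    origin: tuple[str, int]

    def __post_init__(self) -> None:
        if self.values.shape != (36, WINDOW):
            raise ValueError(
                f"window must be 36 x {WINDOW}, got {self.values.shape}"
            )
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class TrainSpec:
    optimizer: str = "sgd"
    learning_rate: float = 3e-3
    batch_size: int = 128
    epochs: int = 20
    seed: int = 0
    backbone: str = "tiny"


@dataclass
class InferenceTrace:
    """Per-sample class / confidence traces of the rolling window.

    ``o`` is the (possibly interpolated) class trace, ``c`` the predicted-
    class confidence and ``s = o * c`` the class-1 confidence trace.
    ``s_hat`` and ``s_b`` are filled by :func:`postprocess_trace`.
    """

    patient_id: str
    o: np.ndarray
    c: np.ndarray
    s: np.ndarray
    stride: int = 1
    s_hat: np.ndarray | None = field(default=None, repr=False)
    s_b: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# training-set construction


def negative_intervals(
    starts: np.ndarray, t: int, window: int = WINDOW, guard_margin: int = GUARD_MARGIN
) -> list[tuple[int, int]]:
    """Half-open intervals guaranteed free of swallow activity.

    Gaps between consecutive annotated swallows (each swallow occupying
    [start, start + window)) are shrunk by the guard margin on both sides;
    the tail after the last swallow is included (shrunk on its left only).
    The segment before the first annotation is not used: the recording may
    begin mid-swallow and its freedom from activity cannot be vouched for.
    """
    starts = np.sort(np.asarray(starts, dtype=np.int64))
    if starts.size == 0:
        return [(0, t)] if t > 0 else []
    intervals: list[tuple[int, int]] = []
    for a, b in zip(starts[:-1], starts[1:]):
        lo, hi = int(a) + window + guard_margin, int(b) - guard_margin
        if hi - lo >= window:
            intervals.append((lo, hi))
    lo = int(starts[-1]) + window + guard_margin
    if t - lo >= window:
        intervals.append((lo, t))
    return intervals


def build_training_set(
    recordings: Sequence[PreprocessedRecording],
    annotations: Sequence[AnnotationSet],
    window: int = WINDOW,
    guard_margin: int = GUARD_MARGIN,
    balance: bool = True,
    seed: int = 0,
) -> list[SwallowWindow]:
    """Positive and negative windows from annotated recordings.

    One positive per annotated start (left edge at the start; starts whose
    window would run past the recording end are skipped with a warning);
    negatives tiled non-overlapping inside guarded inter-swallow gaps, then
    subsampled to approximately balanced class sizes.
    """
    ann_by_pid = {a.patient_id: a for a in annotations}
    pos: list[SwallowWindow] = []
    neg: list[SwallowWindow] = []
    for rec in recordings:
        ann = ann_by_pid.get(rec.patient_id)
        starts = ann.starts if ann is not None else np.array([], dtype=np.int64)
        for s in starts:
            if s + window > rec.t:
                logger.warning(
                    "patient %s: swallow at %d runs past the recording end, "
                    "window skipped", rec.patient_id, s,
                )
                continue
            pos.append(
                SwallowWindow(
                    values=rec.values[:, s : s + window],
                    label=1,
                    origin=(rec.patient_id, int(s)),
                )
            )
        for lo, hi in negative_intervals(starts, rec.t, window, guard_margin):
            for a in range(lo, hi - window + 1, window):
                neg.append(
                    SwallowWindow(
                        values=rec.values[:, a : a + window],
                        label=0,
                        origin=(rec.patient_id, int(a)),
                    )
                )
    if balance and pos and neg:
        rng = np.random.default_rng(seed)
        n = min(len(pos), len(neg))
        if len(neg) > n:
            keep = rng.choice(len(neg), size=n, replace=False)
            neg = [neg[i] for i in sorted(keep)]
        elif len(pos) > n:
            keep = rng.choice(len(pos), size=n, replace=False)
            pos = [pos[i] for i in sorted(keep)]
    return pos + neg


def windows_to_arrays(
    windows: Sequence[SwallowWindow],
) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([w.values for w in windows]).astype(np.float32)
    y = np.array([w.label for w in windows], dtype=np.int64)
    return X, y


# ---------------------------------------------------------------------------
# classifier


class WindowClassifier(ClassifierMixin, BaseEstimator):
    """Binary swallow / non-swallow classifier over 36 x 500 windows.

    Parameters follow the detection method's training recipe (SGD,
    learning rate 3e-3, batch size 128, 20 epochs).  ``X`` for ``fit`` and
    ``predict`` is an array (n, 36, 500) on the 0-255 scale.
    """

    def __init__(
        self,
        backbone: str = "tiny",
        learning_rate: float = 3e-3,
        batch_size: int = 128,
        epochs: int = 20,
        ensemble_size: int = 5,
        random_state: int | None = None,
    ) -> None:
        self.backbone = backbone
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.ensemble_size = ensemble_size
        self.random_state = random_state

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != 36:
            raise ValueError(f"expected windows (n, 36, {WINDOW}), got {X.shape}")
        shape = BACKBONES[self.backbone]["input_shape"]
        small = resize_windows(X, shape)
        return (small / 255.0).reshape(len(X), -1)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "WindowClassifier":
        if self.backbone not in BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; "
                f"available: {sorted(BACKBONES)}"
            )
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                "training set must contain both swallow and non-swallow windows"
            )
        feats = self._features(X)
        # Standardize with a variance floor: plain z-scoring would divide
        # near-constant background pixels by their tiny noise sd and turn
        # them into dominant inputs, making the confidence trace erratic
        # on partially overlapping windows.  Flooring the scale at the
        # mean pixel sd keeps optimization well-conditioned while leaving
        # background pixels quiet.
        self.center_ = feats.mean(axis=0)
        sd = feats.std(axis=0)
        self.scale_ = np.maximum(sd, sd.mean() if sd.mean() > 0 else 1.0)
        feats = (feats - self.center_) / self.scale_
        # The tiny backbone is a small committee of MLPs differing only in
        # initialization; averaging their probabilities smooths the
        # confidence response over window offsets, which keeps each
        # swallow a single run after trace thresholding.
        base = 0 if self.random_state is None else int(self.random_state)
        members = []
        with warnings.catch_warnings():
            # max_iter is the epoch budget, not a convergence criterion
            warnings.simplefilter("ignore", ConvergenceWarning)
            for j in range(self.ensemble_size):
                mlp = MLPClassifier(
                    hidden_layer_sizes=BACKBONES[self.backbone][
                        "hidden_layer_sizes"
                    ],
                    solver="sgd",
                    learning_rate_init=self.learning_rate,
                    batch_size=min(self.batch_size, len(feats)),
                    max_iter=self.epochs,
                    momentum=0.9,
                    nesterovs_momentum=True,
                    shuffle=True,
                    random_state=(base * 1000 + j) % (2**31),
                )
                mlp.fit(feats, y)
                members.append(mlp)
        self.model_ = members
        self.classes_ = members[0].classes_
        acc = float(
            np.mean(
                self.classes_[
                    np.argmax(
                        np.mean([m.predict_proba(feats) for m in members], axis=0),
                        axis=1,
                    )
                ]
                == y
            )
        )
        self.training_log_ = {
            "loss_curves": [[float(v) for v in m.loss_curve_] for m in members],
            "final_loss": float(np.mean([m.loss_ for m in members])),
            "train_accuracy": acc,
        }
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        feats = (self._features(X) - self.center_) / self.scale_
        return np.mean([m.predict_proba(feats) for m in self.model_], axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_classifier(
    windows: Sequence[SwallowWindow], spec: TrainSpec | None = None
) -> WindowClassifier:
    """Train a window classifier from :class:`SwallowWindow` samples."""
    spec = spec or TrainSpec()
    X, y = windows_to_arrays(windows)
    clf = WindowClassifier(
        backbone=spec.backbone,
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        epochs=spec.epochs,
        random_state=spec.seed,
    )
    return clf.fit(X, y)


# ---------------------------------------------------------------------------
# inference


def rolling_inference(
    clf: WindowClassifier,
    rec: PreprocessedRecording,
    stride: int = 1,
    window: int = WINDOW,
    batch_size: int = 512,
) -> InferenceTrace:
    """Slide a window over the recording and collect the confidence trace.

    Window i covers [i, i + 500).  For stride > 1 the class and confidence
    traces are linearly interpolated back to per-sample resolution before
    forming s = o * c.
    """
    t = rec.t
    if t < window:
        raise ValueError(f"recording length {t} shorter than window {window}")
    positions = np.arange(0, t - window + 1, stride)
    views = np.lib.stride_tricks.sliding_window_view(
        rec.values, window, axis=1
    )  # (36, n_all, 500)
    p1 = np.empty(len(positions))
    for lo in range(0, len(positions), batch_size):
        chunk = positions[lo : lo + batch_size]
        batch = np.ascontiguousarray(views[:, chunk].transpose(1, 0, 2))
        p1[lo : lo + batch_size] = clf.predict_proba(batch)[:, 1]
    o_raw = (p1 > 0.5).astype(float)
    c_raw = np.where(o_raw > 0, p1, 1.0 - p1)
    if stride > 1 and len(positions) > 1:
        full = np.arange(positions[-1] + 1)
        o = np.interp(full, positions, o_raw)
        c = np.interp(full, positions, c_raw)
    else:
        o, c = o_raw, c_raw
    return InferenceTrace(patient_id=rec.patient_id, o=o, c=c, s=o * c, stride=stride)


def extract_runs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive [first, last] spans of maximal runs of ones."""
    binary = np.asarray(binary).astype(bool)
    if binary.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], binary.view(np.int8), [0]))))
    return [(int(a), int(b) - 1) for a, b in zip(edges[::2], edges[1::2])]


def postprocess_trace(
    trace: InferenceTrace,
    smooth_w: int = 20,
    threshold: float = 0.2,
) -> DetectionResult:
    """Smooth, binarize and reduce the confidence trace to detections.

    s_hat = moving_average(s, 20); s_b = 1 where s_hat > 0.2; each maximal
    run of ones in s_b is one detected swallow whose predicted start is the
    first argmax of the raw trace s within the run's sample span, and whose
    confidence is that maximum.
    """
    s = np.asarray(trace.s, dtype=float)
    if len(s) < smooth_w:
        trace.s_hat = np.zeros(0)
        trace.s_b = np.zeros(0, dtype=bool)
        return DetectionResult(
            patient_id=trace.patient_id,
            predicted_starts=np.array([], dtype=np.int64),
            confidences=np.array([]),
            method="dl",
        )
    s_hat = moving_average(s, smooth_w)
    s_b = s_hat > threshold
    trace.s_hat = s_hat
    trace.s_b = s_b
    starts: list[int] = []
    confs: list[float] = []
    for a, b in extract_runs(s_b):
        span = s[a : b + 1]
        idx = a + int(np.argmax(span))  # first index on ties
        starts.append(idx)
        confs.append(float(s[idx]))
    return DetectionResult(
        patient_id=trace.patient_id,
        predicted_starts=np.array(starts, dtype=np.int64),
        confidences=np.array(confs),
        method="dl",
    )


# ---------------------------------------------------------------------------
# end-to-end detector estimator


class RollingWindowDetector(BaseEstimator):
    """Trainable swallow-start detector (classifier + trace post-processing).

    ``fit`` takes preprocessed recordings with annotations, builds the
    window training set and trains the classifier; ``predict`` runs rolling
    inference on one recording and returns a :class:`DetectionResult`.
    """

    def __init__(
        self,
        backbone: str = "tiny",
        window: int = WINDOW,
        guard_margin: int = GUARD_MARGIN,
        stride: int = 1,
        smooth_window: int = 20,
        threshold: float = 0.2,
        learning_rate: float = 3e-3,
        batch_size: int = 128,
        epochs: int = 20,
        random_state: int | None = None,
    ) -> None:
        self.backbone = backbone
        self.window = window
        self.guard_margin = guard_margin
        self.stride = stride
        self.smooth_window = smooth_window
        self.threshold = threshold
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def fit(
        self,
        X: Sequence[PreprocessedRecording],
        y: Sequence[AnnotationSet],
    ) -> "RollingWindowDetector":
        windows = build_training_set(
            X, y,
            window=self.window,
            guard_margin=self.guard_margin,
            seed=self.random_state or 0,
        )
        n_pos = sum(w.label for w in windows)
        logger.info(
            "training set: %d positive / %d negative windows",
            n_pos, len(windows) - n_pos,
        )
        Xw, yw = windows_to_arrays(windows)
        self.classifier_ = WindowClassifier(
            backbone=self.backbone,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            random_state=self.random_state,
        ).fit(Xw, yw)
        return self

    def predict(self, rec: PreprocessedRecording) -> DetectionResult:
        check_is_fitted(self, "classifier_")
        trace = rolling_inference(
            self.classifier_, rec, stride=self.stride, window=self.window
        )
        return postprocess_trace(
            trace, smooth_w=self.smooth_window, threshold=self.threshold
        )

    def predict_trace(self, rec: PreprocessedRecording) -> InferenceTrace:
        check_is_fitted(self, "classifier_")
        return rolling_inference(
            self.classifier_, rec, stride=self.stride, window=self.window
        )
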