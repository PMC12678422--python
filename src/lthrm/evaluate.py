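"""Tolerance-window matching, detection metrics and patient-grouped CV.

A predicted swallow counts as a true positive when it falls inside a
tolerance window of width d around the target:

* start mode (classifier detector): window [y - d/2, y + d/2] around the
  annotated start y, endpoints inclusive;
* event mode (threshold detector, which fires during the swallow rather
  than at its onset): the window is centered 200 samples (4 s) after the
  start, i.e. [y + 200 - d/2, y + 200 + d/2].

Matching is greedy one-to-one by increasing distance to the window center,
which prevents one prediction from absorbing several annotated swallows.
Unmatched predictions are false positives, unmatched annotations false
negatives.  Precision is defined as 0 when there are no predictions so fold
aggregation never fails.

Cross-validation splits by patient: a patient's recordings never appear in
both the training and the evaluation side of a fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io import AnnotationSet, DetectionResult, PreprocessedRecording

logger = logging.getLogger(__name__)


@dataclass
class MatchSpec:
    d: int = 400
    mode: str = "start"  # "start" or "event"
    event_offset: int = 200

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("tolerance window d must be positive")
        if self.mode not in {"start", "event"}:
            raise ValueError("mode must be 'start' or 'event'")

    @property
    def offset(self) -> int:
        return self.event_offset if self.mode == "event" else 0


@dataclass
class MetricsResult:
    tp: int
    fp: int
    fn: int
    matches: list[tuple[int, int]] = field(default_factory=list, repr=False)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def match_detections(
    true_starts: Sequence[int] | np.ndarray,
    predicted: Sequence[int] | np.ndarray | DetectionResult,
    spec: MatchSpec | None = None,
) -> MetricsResult:
    """Greedy one-to-one matching of predictions to annotated swallows."""
    spec = spec or MatchSpec()
    if isinstance(predicted, DetectionResult):
        predicted = predicted.predicted_starts
    truths = np.asarray(true_starts, dtype=np.int64)
    preds = np.asarray(predicted, dtype=np.int64)
    centers = truths + spec.offset
    half = spec.d / 2.0

    # candidate pairs within the window, ordered by |pred - center|,
    # ties broken by prediction index then truth index (deterministic)
    pairs: list[tuple[float, int, int]] = []
    for pi, p in enumerate(preds):
        dist = np.abs(p - centers)
        for ti in np.nonzero(dist <= half)[0]:
            pairs.append((float(dist[ti]), pi, int(ti)))
    pairs.sort()

    used_p: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches.append((int(preds[pi]), int(truths[ti])))

    tp = len(matches)
    return MetricsResult(
        tp=tp, fp=len(preds) - tp, fn=len(truths) - tp, matches=matches
    )


def pooled_metrics(results: Sequence[MetricsResult]) -> MetricsResult:
    """Sum TP/FP/FN over several recordings."""
    return MetricsResult(
        tp=sum(r.tp for r in results),
        fp=sum(r.fp for r in results),
        fn=sum(r.fn for r in results),
    )


@dataclass
class CVResult:
    """Per-fold pooled metrics for one tolerance spec, plus mean +/- sd."""

    spec: MatchSpec
    folds: list[MetricsResult]

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.folds], dtype=float)
        return float(vals.mean()), float(vals.std(ddof=0))

    @property
    def precision(self) -> tuple[float, float]:
        return self._agg("precision")

    @property
    def recall(self) -> tuple[float, float]:
        return self._agg("recall")

    @property
    def f1(self) -> tuple[float, float]:
        return self._agg("f1")


def make_patient_folds(
    patient_ids: Sequence[str], k: int = 5, seed: int = 0
) -> list[list[str]]:
    """Random partition of patients into k folds (patients never split)."""
    unique = sorted(set(patient_ids))
    if len(unique) < k:
        raise ValueError(f"need at least {k} patients, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(unique[idx])
    return [sorted(f) for f in folds]


def grouped_cv(
    recordings: Sequence[PreprocessedRecording],
    annotations: Sequence[AnnotationSet],
    detector_factory: Callable[[int], object],
    k: int = 5,
    seed: int = 0,
    match_specs: Sequence[MatchSpec] | None = None,
) -> dict[str, CVResult]:
    """Patient-grouped k-fold cross-validation of a trainable detector.

    ``detector_factory(fold_seed)`` must return an object with
    ``fit(recordings, annotations)`` and ``predict(recording)``.  Metrics
    are pooled over each held-out fold's recordings and aggregated as
    mean +/- sd across folds.  Returns one :class:`CVResult` per match
    spec, keyed ``"{mode}_d{d}"``.
    """
    if match_specs is None:
        match_specs = [MatchSpec(d=400, mode="start")]
    ann_by_pid = {a.patient_id: a for a in annotations}
    missing = [r.patient_id for r in recordings if r.patient_id not in ann_by_pid]
    if missing:
        raise ValueError(f"no annotations for patient(s): {missing}")

    folds = make_patient_folds([r.patient_id for r in recordings], k=k, seed=seed)
    per_spec: dict[str, list[MetricsResult]] = {
        f"{s.mode}_d{s.d}": [] for s in match_specs
    }
    seed_seq = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(k)]

    for fold_idx, held_out in enumerate(folds):
        held = set(held_out)
        train_recs = [r for r in recordings if r.patient_id not in held]
        train_anns = [ann_by_pid[r.patient_id] for r in train_recs]
        test_recs = [r for r in recordings if r.patient_id in held]

        detector = detector_factory(fold_seeds[fold_idx])
        detector.fit(train_recs, train_anns)
        predictions = {r.patient_id: detector.predict(r) for r in test_recs}
        logger.info(
            "fold %d/%d: trained on %d recordings, evaluated on %s",
            fold_idx + 1, k, len(train_recs), held_out,
        )

        for s in match_specs:
            fold_result = pooled_metrics(
                [
                    match_detections(
                        ann_by_pid[pid].starts, det.predicted_starts, s
                    )
                    for pid, det in predictions.items()
                ]
            )
            per_spec[f"{s.mode}_d{s.d}"].append(fold_result)

    return {
        f"{s.mode}_d{s.d}": CVResult(spec=s, folds=per_spec[f"{s.mode}_d{s.d}"])
        for s in match_specs
    }
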