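"""Threshold-based swallow detector (the non-ML baseline).

Pressure along the esophagus rises characteristically during a swallow, so a
chain of simple morphological operations already localizes swallow events:

1. binarize the smoothed mmHg matrix with a strict ``> 80`` mmHg threshold;
2. apply a vertical (across-sensor) moving sum of width 20 to highlight runs
   of consecutive active sensors (zero-padded past the last row);
3. sum each column across all 36 sensors into an activity trace r;
4. smooth r with a moving average of width 100;
5. find peaks strictly above a threshold, at least ``peak_min_distance``
   samples apart.

The detector aims at the body of the swallow rather than its start, so it is
evaluated in "event" mode (tolerance window centered 200 samples after the
annotated start, see :mod:`lthrm.evaluate`).

The binarization threshold is applied on the mmHg scale by default: 80 mmHg
is a plausible contraction pressure, whereas 80 on the 0-255 scale would
correspond to about -43 mmHg and binarize nearly everything.  The peak
threshold itself is a free parameter; the default 60 corresponds to roughly
three fully active sensors sustained across the smoothing window, and
:meth:`ThresholdDetector.fit` can calibrate it on annotated data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .evaluate import MatchSpec, match_detections
from .io import AnnotationSet, DetectionResult, PreprocessedRecording
from .preprocess import moving_average

N_SENSORS = 36


@dataclass
class BaselineParams:
    binarize_threshold: float = 80.0
    domain: str = "mmhg"  # "mmhg" or "scaled"
    vertical_window: int = 20
    smooth_window: int = 100
    peak_threshold: float = 60.0
    peak_min_distance: int = 250

    def __post_init__(self) -> None:
        for name in (
            "binarize_threshold",
            "vertical_window",
            "smooth_window",
            "peak_threshold",
            "peak_min_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.domain not in {"mmhg", "scaled"}:
            raise ValueError("domain must be 'mmhg' or 'scaled'")


def binarize(values: np.ndarray, threshold: float = 80.0) -> np.ndarray:
    """Strict threshold: 1 where value > threshold, else 0."""
    return (np.asarray(values, dtype=float) > threshold).astype(float)


def vertical_moving_sum(binary: np.ndarray, w_v: int = 20) -> np.ndarray:
    """Across-sensor moving sum, zero-padded below the last row.

    out[i, j] = sum_{k=i}^{i+w_v-1} binary[k, j], with rows past the matrix
    treated as zero, so 0 <= out <= w_v everywhere.
    """
    binary = np.asarray(binary, dtype=float)
    if binary.shape[0] != N_SENSORS:
        raise ValueError(f"expected {N_SENSORS} sensor rows")
    padded = np.vstack([binary, np.zeros((w_v - 1, binary.shape[1]))])
    csum = np.cumsum(padded, axis=0)
    csum = np.vstack([np.zeros((1, binary.shape[1])), csum])
    return csum[w_v:] - csum[:-w_v]


def column_activity(moving_sums: np.ndarray) -> np.ndarray:
    """Column sum across all sensors: r[j] = sum_i out[i, j]."""
    return np.asarray(moving_sums, dtype=float).sum(axis=0)


def activity_trace(
    values: np.ndarray,
    binarize_threshold: float = 80.0,
    vertical_window: int = 20,
    smooth_window: int = 100,
) -> np.ndarray:
    """Full chain binarize -> vertical sum -> column sum -> smooth."""
    mb = binarize(values, binarize_threshold)
    ms = vertical_moving_sum(mb, vertical_window)
    r = column_activity(ms)
    return moving_average(r, smooth_window)


def detect_peaks(
    smoothed_activity: np.ndarray,
    peak_threshold: float,
    peak_min_distance: int,
    patient_id: str = "",
    vertical_window: int = 20,
) -> DetectionResult:
    """Peaks strictly above ``peak_threshold``, >= ``peak_min_distance`` apart.

    On conflicts the higher peak wins.  The reported confidence is the peak
    height rescaled by the maximum attainable activity 36 * w_v.
    """
    r_hat = np.asarray(smoothed_activity, dtype=float)
    # find_peaks' height test is inclusive; nextafter enforces strict >
    peaks, props = find_peaks(
        r_hat,
        height=np.nextafter(peak_threshold, np.inf),
        distance=peak_min_distance,
    )
    conf = np.clip(props["peak_heights"] / (N_SENSORS * vertical_window), 0.0, 1.0)
    return DetectionResult(
        patient_id=patient_id,
        predicted_starts=peaks.astype(np.int64),
        confidences=conf,
        method="baseline",
    )


class ThresholdDetector(BaseEstimator):
    """sklearn-style wrapper around the threshold detection chain.

    ``fit`` is optional: with no data it freezes the configured parameters;
    given preprocessed recordings and annotations it calibrates the peak
    threshold by sweeping a grid and keeping the value with the best F1 in
    event mode.
    """

    def __init__(
        self,
        binarize_threshold: float = 80.0,
        domain: str = "mmhg",
        vertical_window: int = 20,
        smooth_window: int = 100,
        peak_threshold: float = 60.0,
        peak_min_distance: int = 250,
        calibration_grid: Sequence[float] | None = None,
        d: int = 400,
    ) -> None:
        self.binarize_threshold = binarize_threshold
        self.domain = domain
        self.vertical_window = vertical_window
        self.smooth_window = smooth_window
        self.peak_threshold = peak_threshold
        self.peak_min_distance = peak_min_distance
        self.calibration_grid = calibration_grid
        self.d = d

    def fit(
        self,
        X: Sequence[PreprocessedRecording] | None = None,
        y: Sequence[AnnotationSet] | None = None,
    ) -> "ThresholdDetector":
        BaselineParams(
            binarize_threshold=self.binarize_threshold,
            domain=self.domain,
            vertical_window=self.vertical_window,
            smooth_window=self.smooth_window,
            peak_threshold=self.peak_threshold,
            peak_min_distance=self.peak_min_distance,
        )
        self.peak_threshold_ = float(self.peak_threshold)
        if X is not None and y is not None:
            self.peak_threshold_ = self._calibrate(list(X), list(y))
        return self

    def _calibrate(
        self, recs: list[PreprocessedRecording], anns: list[AnnotationSet]
    ) -> float:
        grid = self.calibration_grid
        if grid is None:
            grid = np.arange(10.0, 361.0, 10.0)
        traces = [self._trace(rec) for rec in recs]
        spec = MatchSpec(d=self.d, mode="event")
        best_thr, best_f1 = float(self.peak_threshold), -1.0
        for thr in grid:
            tp = fp = fn = 0
            for trace, ann in zip(traces, anns):
                det = detect_peaks(
                    trace, thr, self.peak_min_distance,
                    vertical_window=self.vertical_window,
                )
                m = match_detections(ann.starts, det.predicted_starts, spec)
                tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 > best_f1:
                best_thr, best_f1 = float(thr), f1
        return best_thr

    def _trace(self, rec: PreprocessedRecording) -> np.ndarray:
        values = rec.values_mmhg if self.domain == "mmhg" else rec.values
        return activity_trace(
            values,
            binarize_threshold=self.binarize_threshold,
            vertical_window=self.vertical_window,
            smooth_window=self.smooth_window,
        )

    def predict(self, rec: PreprocessedRecording) -> DetectionResult:
        thr = getattr(self, "peak_threshold_", self.peak_threshold)
        return detect_peaks(
            self._trace(rec),
            thr,
            self.peak_min_distance,
            patient_id=rec.patient_id,
            vertical_window=self.vertical_window,
        )

    # alias used by the CLI
    detect = predict


def detect_baseline(
    rec: PreprocessedRecording, params: BaselineParams | None = None
) -> DetectionResult:
    """One-shot functional interface over :class:`ThresholdDetector`."""
    params = params or BaselineParams()
    det = ThresholdDetector(
        binarize_threshold=params.binarize_threshold,
        domain=params.domain,
        vertical_window=params.vertical_window,
        smooth_window=params.smooth_window,
        peak_threshold=params.peak_threshold,
        peak_min_distance=params.peak_min_distance,
    ).fit()
    return det.predict(rec)
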