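"""Domain types and file I/O for long-term high-resolution manometry (LTHRM).

A recording is the pressure matrix produced by a catheter with 36
circumferential sensors spaced 1 cm apart, sampled at 50 Hz: a 36 x t array
of pressures in mmHg.  Swallow annotations are sample indices of upper
esophageal sphincter (UES) relaxation, the physiological marker of swallow
onset.

Interchange formats:

* recordings  -- CSV (time-major, columns ``sensor_01`` .. ``sensor_36``) or
  HDF5 (dataset ``/pressures`` shaped 36 x t, attrs ``patient_id`` and
  ``sampling_rate_hz``);
* annotations -- TSV with columns ``patient_id`` and ``start_index``.

All indices are 0-based and intervals half-open unless stated otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_SENSORS = 36
DEFAULT_SAMPLING_RATE_HZ = 50.0

_CSV_COLUMNS = [f"sensor_{i + 1:02d}" for i in range(N_SENSORS)]


class FormatError(ValueError):
    """A file does not conform to the declared interchange format."""


@dataclass
class ManometryRecording:
    """One LTHRM recording: 36 sensors x t samples of pressure in mmHg."""

    patient_id: str
    pressures: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.pressures.ndim != 2 or self.pressures.shape[0] != N_SENSORS:
            raise FormatError(
                f"expected a {N_SENSORS} x t pressure matrix, got shape "
                f"{self.pressures.shape}"
            )
        if self.pressures.shape[1] < 1:
            raise FormatError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.pressures)):
            raise FormatError("pressure matrix contains NaN or infinite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def t(self) -> int:
        return self.pressures.shape[1]


@dataclass
class AnnotationSet:
    """Expert swallow-start annotations (UES relaxation onsets) for one patient.

    ``starts`` is kept sorted, deduplicated and strictly increasing.
    """

    patient_id: str
    starts: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        if starts.size and starts.min() < 0:
            raise ValueError("annotation indices must be non-negative")
        uniq = np.unique(starts)
        if uniq.size != starts.size:
            logger.warning(
                "patient %s: %d duplicate annotation(s) removed",
                self.patient_id,
                starts.size - uniq.size,
            )
        self.starts = uniq

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class PreprocessedRecording:
    """Smoothed/clipped recording on both the mmHg and the 0-255 scale.

    ``values_mmhg`` is the moving-average-smoothed matrix clipped to the
    physiologically valid range; ``values`` is its affine rescale onto
    [0, 255].  Both have length t' = t - w + 1 where w is the smoothing
    window.
    """

    patient_id: str
    values: np.ndarray
    values_mmhg: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    @property
    def t(self) -> int:
        return self.values.shape[1]


@dataclass
class DetectionResult:
    """Predicted swallow starts with one confidence in [0, 1] per start."""

    patient_id: str
    predicted_starts: np.ndarray
    confidences: np.ndarray
    method: str = "dl"

    def __post_init__(self) -> None:
        self.predicted_starts = np.asarray(self.predicted_starts, dtype=np.int64)
        self.confidences = np.asarray(self.confidences, dtype=float)
        if self.predicted_starts.shape != self.confidences.shape:
            raise ValueError("starts and confidences must have equal length")
        if self.predicted_starts.size > 1 and np.any(
            np.diff(self.predicted_starts) < 0
        ):
            order = np.argsort(self.predicted_starts, kind="stable")
            self.predicted_starts = self.predicted_starts[order]
            self.confidences = self.confidences[order]

    def __len__(self) -> int:
        return len(self.predicted_starts)


# ---------------------------------------------------------------------------
# recordings


def read_recording(path: str | Path, format: str | None = None) -> ManometryRecording:
    """Read a recording from CSV or HDF5 (inferred from the suffix)."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown recording format: {format!r}")


def write_recording(
    rec: ManometryRecording, path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if format == "csv":
        df = pd.DataFrame(rec.pressures.T, columns=_CSV_COLUMNS)
        # %.17g keeps float64 values exact through the text round trip
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("pressures", data=rec.pressures)
            ds.attrs["patient_id"] = rec.patient_id
            ds.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
    else:
        raise ValueError(f"unknown recording format: {format!r}")


def _read_csv(path: Path) -> ManometryRecording:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: could not parse CSV: {exc}") from exc
    if list(df.columns) != _CSV_COLUMNS:
        raise FormatError(
            f"{path}: expected {N_SENSORS} columns named sensor_01..sensor_36, "
            f"got {len(df.columns)} column(s)"
        )
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float, copy=False)) if values.dtype.kind in "fc" else None
    try:
        matrix = values.astype(float).T
    except (TypeError, ValueError) as exc:
        # locate first non-numeric cell for the error message
        for i, row in enumerate(values):
            try:
                np.asarray(row, dtype=float)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric value in data row {i}"
                ) from exc
        raise FormatError(f"{path}: non-numeric data") from exc
    if bad is not None and bad.any():
        i = int(np.argwhere(bad)[0, 0])
        raise FormatError(f"{path}: non-finite value in data row {i}")
    return ManometryRecording(patient_id=path.stem, pressures=matrix)


def _read_hdf5(path: Path) -> ManometryRecording:
    with h5py.File(path, "r") as f:
        if "pressures" not in f:
            raise FormatError(f"{path}: missing dataset /pressures")
        ds = f["pressures"]
        matrix = np.asarray(ds, dtype=float)
        patient_id = str(ds.attrs.get("patient_id", path.stem))
        rate = float(ds.attrs.get("sampling_rate_hz", DEFAULT_SAMPLING_RATE_HZ))
    return ManometryRecording(
        patient_id=patient_id, pressures=matrix, sampling_rate_hz=rate
    )


# ---------------------------------------------------------------------------
# annotations


def read_annotation_table(path: str | Path) -> dict[str, AnnotationSet]:
    """Read a TSV of ``patient_id<TAB>start_index`` rows, one set per patient."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "start_index"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: annotation TSV needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    idx = pd.to_numeric(df["start_index"], errors="coerce")
    if idx.isna().any():
        row = int(idx.isna().idxmax())
        raise FormatError(f"{path}: non-integer start_index in row {row}")
    if (idx < 0).any():
        raise ValueError(f"{path}: negative start_index")
    out: dict[str, AnnotationSet] = {}
    for pid, group in df.assign(start_index=idx.astype(np.int64)).groupby(
        "patient_id", sort=True
    ):
        out[str(pid)] = AnnotationSet(
            patient_id=str(pid), starts=group["start_index"].to_numpy()
        )
    return out


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read annotations for a single patient (error if the file mixes patients)."""
    table = read_annotation_table(path)
    if len(table) != 1:
        raise FormatError(
            f"{path}: expected annotations for exactly one patient, "
            f"found {sorted(table)}"
        )
    return next(iter(table.values()))


def write_annotations(
    anns: AnnotationSet | Sequence[AnnotationSet], path: str | Path
) -> None:
    if isinstance(anns, AnnotationSet):
        anns = [anns]
    rows = [
        {"patient_id": a.patient_id, "start_index": int(s)}
        for a in anns
        for s in a.starts
    ]
    pd.DataFrame(rows, columns=["patient_id", "start_index"]).to_csv(
        path, sep="\t", index=False
    )


def write_detections(
    results: DetectionResult | Sequence[DetectionResult], path: str | Path
) -> None:
    """Write detections as TSV ``patient_id, start_index, confidence, method``."""
    if isinstance(results, DetectionResult):
        results = [results]
    rows = [
        {
            "patient_id": r.patient_id,
            "start_index": int(s),
            "confidence": float(c),
            "method": r.method,
        }
        for r in results
        for s, c in zip(r.predicted_starts, r.confidences)
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "start_index", "confidence", "method"]
    ).to_csv(path, sep="\t", index=False)


def read_detections(path: str | Path) -> dict[str, DetectionResult]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if "confidence" not in df.columns:  # e.g. an annotation TSV reused as input
        df = df.assign(confidence=1.0)
    out: dict[str, DetectionResult] = {}
    for pid, group in df.groupby("patient_id", sort=True):
        out[str(pid)] = DetectionResult(
            patient_id=str(pid),
            predicted_starts=group["start_index"].to_numpy(dtype=np.int64),
            confidences=group["confidence"].to_numpy(dtype=float),
            method=str(group["method"].iloc[0]) if "method" in group else "unknown",
        )
    return out
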