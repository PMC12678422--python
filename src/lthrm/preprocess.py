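"""Smoothing, clipping, rescaling and window-resizing primitives.

The raw pressure matrix M (36 x t, mmHg) is smoothed per sensor row with a
left-aligned moving average of width w (default 30 samples = 0.6 s at
50 Hz), clipped to the physiologically valid range [-200, 300] mmHg to
remove extreme outliers, and affinely rescaled onto [0, 255].  The smoothed
timeline has length t' = t - w + 1; annotated swallow starts map onto it
unchanged because the shift (< w) is negligible against the evaluation
tolerance windows.

Resizing uses separable, corner-aligned bilinear interpolation so that a
constant image stays exactly constant and the output range never leaves the
input range (up to floating-point epsilon).
"""

from __future__ import annotations

import numpy as np

from .io import ManometryRecording, PreprocessedRecording

DEFAULT_SMOOTH_WINDOW = 30
CLIP_LO = -200.0
CLIP_HI = 300.0


def moving_average(values: np.ndarray, w: int, axis: int = -1) -> np.ndarray:
    """Left-aligned moving average: out[j] = mean(values[j .. j+w-1]).

    Output length along ``axis`` is n - w + 1.  Raises ValueError when the
    input is shorter than the window.
    """
    values = np.asarray(values, dtype=float)
    if w < 1:
        raise ValueError("window must be >= 1")
    n = values.shape[axis]
    if n < w:
        raise ValueError(f"input length {n} shorter than window {w}")
    windows = np.lib.stride_tricks.sliding_window_view(values, w, axis=axis)
    return windows.mean(axis=-1)


def clip_rescale(
    values: np.ndarray, lo: float = CLIP_LO, hi: float = CLIP_HI
) -> np.ndarray:
    """Clip to [lo, hi] mmHg and map affinely onto [0, 255] (float, no
    integer quantization)."""
    if lo >= hi:
        raise ValueError(f"clip range invalid: lo={lo} >= hi={hi}")
    clipped = np.clip(np.asarray(values, dtype=float), lo, hi)
    return 255.0 * (clipped - lo) / (hi - lo)


def preprocess_recording(
    rec: ManometryRecording,
    w: int = DEFAULT_SMOOTH_WINDOW,
    lo: float = CLIP_LO,
    hi: float = CLIP_HI,
) -> PreprocessedRecording:
    """Smooth, clip and rescale a recording.

    Returns both the clipped mmHg matrix (used by the threshold detector,
    whose 80 mmHg binarization threshold is physiological) and the 0-255
    matrix (the classifier's input scale).
    """
    smoothed = moving_average(rec.pressures, w, axis=1)
    clipped = np.clip(smoothed, lo, hi)
    scaled = 255.0 * (clipped - lo) / (hi - lo)
    return PreprocessedRecording(
        patient_id=rec.patient_id,
        values=scaled,
        values_mmhg=clipped,
        sampling_rate_hz=rec.sampling_rate_hz,
    )


def _interp_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_in, n_out) corner-aligned bilinear interpolation matrix."""
    if n_in == n_out:
        return np.eye(n_in)
    x = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(x).astype(int)
    lo = np.minimum(lo, n_in - 2)
    frac = x - lo
    w = np.zeros((n_in, n_out))
    w[lo, np.arange(n_out)] = 1.0 - frac
    w[lo + 1, np.arange(n_out)] = frac
    return w


def resize_window(
    img: np.ndarray,
    out_shape: tuple[int, int],
    in_shape: tuple[int, int] | None = (36, 500),
) -> np.ndarray:
    """Bilinear resize of one window; ``in_shape=None`` skips the shape check."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D window")
    if in_shape is not None and img.shape != in_shape:
        raise ValueError(f"expected window of shape {in_shape}, got {img.shape}")
    return resize_windows(img[None], out_shape)[0]


def resize_windows(windows: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resize a batch (n, h_in, w_in) -> (n, h_out, w_out), separably."""
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3:
        raise ValueError("expected a batch of 2-D windows")
    h_out, w_out = out_shape
    rows = _interp_weights(windows.shape[1], h_out)  # (h_in, h_out)
    cols = _interp_weights(windows.shape[2], w_out)  # (w_in, w_out)
    out = np.einsum("ho,nhw->now", rows, windows, optimize=True)
    return np.einsum("nhw,wo->nho", out, cols, optimize=True)


def time_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Expose the 1-D interpolation operator (used by fast rolling inference)."""
    return _interp_weights(n_in, n_out)
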