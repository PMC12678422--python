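"""Flat key=value run configuration.

Every tunable of the pipeline lives here under a dotted key; defaults are
the published values of the method wherever one exists.  The file format is
one ``key = value`` pair per line, ``#`` comments allowed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

DEFAULTS: dict[str, Any] = {
    # preprocessing
    "preprocess.smooth_window": 30,
    "preprocess.clip_lo": -200.0,
    "preprocess.clip_hi": 300.0,
    # threshold (non-ML) detector
    "baseline.binarize_threshold": 80.0,
    "baseline.domain": "mmhg",  # or "scaled" (0-255)
    "baseline.vertical_window": 20,
    "baseline.smooth_window": 100,
    "baseline.peak_threshold": 60.0,
    "baseline.peak_min_distance": 250,
    # rolling-window classifier detector
    "detect.window": 500,
    "detect.guard_margin": 250,
    "detect.stride": 1,
    "detect.smooth_window": 20,
    "detect.threshold": 0.2,
    "detect.backbone": "tiny",
    "detect.learning_rate": 3e-3,
    "detect.batch_size": 128,
    "detect.epochs": 20,
    # two-stage clustering
    "cluster.kernel_len": 10,
    "cluster.image_size": 50,
    "cluster.gaussian_sigma": 1.0,
    "cluster.n_components": 30,
    "cluster.k_min": 4,
    "cluster.k_max": 10,
    "cluster.k_strategy": "intra",  # literal lowest mean intra-cluster distance
    "cluster.main_share": 0.15,
    "cluster.special_k": 10,
    # evaluation
    "evaluate.d": 400,
    "evaluate.event_offset": 200,
    "evaluate.folds": 5,
    # synthetic cohort
    "synthetic.n_patients": 20,
    "synthetic.recording_minutes": 10.0,
    "synthetic.swallows_per_minute": 1.0,
    "synthetic.artifacts_per_minute": 0.2,
    "synthetic.noise_sd": 2.0,
    "synthetic.min_gap": 2000,
    # global
    "seed": 0,
}


class RunConfig:
    """Dotted-key configuration with typed defaults and a flat text format."""

    def __init__(self, overrides: dict[str, Any] | None = None) -> None:
        self._values = dict(DEFAULTS)
        if overrides:
            self.update(overrides)

    def update(self, overrides: dict[str, Any]) -> None:
        unknown = sorted(set(overrides) - set(DEFAULTS))
        if unknown:
            raise KeyError(f"unknown config key(s): {', '.join(unknown)}")
        for key, value in overrides.items():
            self._values[key] = _coerce(value, DEFAULTS[key])

    def __getitem__(self, key: str) -> Any:
        return self._values[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self._values.get(key, default)

    def section(self, prefix: str) -> dict[str, Any]:
        """All keys under ``prefix.`` with the prefix stripped."""
        p = prefix + "."
        return {k[len(p):]: v for k, v in self._values.items() if k.startswith(p)}

    def as_dict(self) -> dict[str, Any]:
        return dict(self._values)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        overrides: dict[str, Any] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            overrides[key] = value
        return cls(overrides)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in sorted(self._values.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(value: Any, template: Any) -> Any:
    if isinstance(value, str):
        value = value.strip()
        if isinstance(template, bool):
            return value.lower() in {"1", "true", "yes", "on"}
        if isinstance(template, int):
            return int(value)
        if isinstance(template, float):
            return float(value)
        return value
    if isinstance(template, bool):
        return bool(value)
    if isinstance(template, int) and not isinstance(value, bool):
        return int(value)
    if isinstance(template, float):
        return float(value)
    return value
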