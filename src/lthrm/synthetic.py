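"""Seeded synthetic LTHRM generator with ground-truth annotations.

The generator emulates the statistical structure the detection and
clustering pipeline relies on, not full esophageal physiology:

* region baselines -- upper esophageal sphincter (UES, rows 0-2) around
  70 mmHg, esophageal body (rows 3-32) around 5 mmHg, lower esophageal
  sphincter (LES, rows 33-35) around 25 mmHg;
* per swallow, a transient UES relaxation at the annotated start (the
  clinical definition of swallow onset), an LES relaxation spanning the
  swallow, and a body contraction whose shape depends on the archetype;
* i.i.d. Gaussian sensor noise;
* occasional cough-like artifacts (a brief simultaneous pressure spike
  across all sensors) that are *not* annotated as swallows.

Swallow archetypes model the canonical motility patterns: ``normal``
(peristaltic wave propagating aborally, peak time increasing linearly with
sensor row), ``failed`` (no effective body contraction, pressures staying
below the 80 mmHg contraction threshold), ``simultaneous`` (the whole body
contracts at once, as in esophageal spasm) and ``hypercontractile``
(a normal wave at at least twice the normal amplitude).

The default event density of 1 swallow per minute extrapolates to 1440 per
24 h, inside the 900-1500 range typical of long-term recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AnnotationSet, ManometryRecording

FS = 50.0
N_SENSORS = 36
UES_ROWS = slice(0, 3)
BODY_ROWS = slice(3, 33)
LES_ROWS = slice(33, 36)

UES_BASELINE = 70.0
BODY_BASELINE = 5.0
LES_BASELINE = 25.0

SWALLOW_LEN = 500  # samples (10 s at 50 Hz)
ARTIFACT_LEN = 200


@dataclass
class SwallowArchetype:
    """Parameters of one synthetic event shape (pressures in mmHg)."""

    name: str
    amplitude: float  # body contraction amplitude
    sigma_t: float  # temporal width of the contraction (samples)
    onset: float  # body wave onset relative to swallow start (samples)
    row_delay: float  # per-row propagation delay (samples / sensor)
    ues_depth: float = 65.0  # UES relaxation depth
    ues_sigma: float = 10.0
    ues_center: float = 25.0
    les_depth: float = 20.0
    les_sigma: float = 80.0
    les_center: float = 250.0
    length: int = SWALLOW_LEN


ARCHETYPES: dict[str, SwallowArchetype] = {
    # normal peristalsis: wave crosses 30 body sensors in ~7.5 s
    "normal": SwallowArchetype(
        "normal", amplitude=150.0, sigma_t=30.0, onset=75.0, row_delay=12.5
    ),
    # failed peristalsis: body pressure stays below the contraction threshold
    "failed": SwallowArchetype(
        "failed", amplitude=40.0, sigma_t=30.0, onset=75.0, row_delay=12.5
    ),
    # simultaneous (spastic) contraction: all body rows fire together
    "simultaneous": SwallowArchetype(
        "simultaneous", amplitude=150.0, sigma_t=30.0, onset=150.0, row_delay=0.0
    ),
    # hypercontractile: >= 2x normal amplitude, broader contraction
    "hypercontractile": SwallowArchetype(
        "hypercontractile", amplitude=300.0, sigma_t=45.0, onset=75.0, row_delay=12.5
    ),
    # cough-like artifact: brief spike across *all* sensors, no UES relaxation
    "artifact": SwallowArchetype(
        "artifact",
        amplitude=120.0,
        sigma_t=8.0,
        onset=50.0,
        row_delay=0.0,
        ues_depth=0.0,
        les_depth=0.0,
        length=ARTIFACT_LEN,
    ),
}

DEFAULT_MIXTURE: dict[str, float] = {
    "normal": 0.70,
    "failed": 0.10,
    "simultaneous": 0.10,
    "hypercontractile": 0.10,
}


@dataclass
class SimSpec:
    """Cohort-level simulation settings."""

    n_patients: int = 20
    recording_minutes: float = 10.0
    swallows_per_minute: float = 1.0
    artifacts_per_minute: float = 0.2
    archetype_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    noise_sd: float = 2.0
    ues_baseline: float = UES_BASELINE
    body_baseline: float = BODY_BASELINE
    les_baseline: float = LES_BASELINE
    min_gap: int = 2000  # min start-to-start separation (samples)
    start_margin: int = 200
    end_margin: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.archetype_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"archetype mixture must sum to 1, got {total}")
        unknown = set(self.archetype_mixture) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in mixture: {sorted(unknown)}")

    @property
    def t(self) -> int:
        return int(round(self.recording_minutes * 60 * FS))


def baseline_pressures(spec: SimSpec) -> np.ndarray:
    base = np.empty(N_SENSORS)
    base[UES_ROWS] = spec.ues_baseline
    base[BODY_ROWS] = spec.body_baseline
    base[LES_ROWS] = spec.les_baseline
    return base


def render_swallow(
    archetype: str | SwallowArchetype,
    sampling_rate: float = FS,
    spec: SimSpec | None = None,
) -> tuple[np.ndarray, int]:
    """Deterministic absolute-pressure matrix (36 x L) for one event.

    Returns the matrix and the canonical start offset within it (0: the
    UES relaxation onset is the left edge).  All temporal shapes are
    Gaussian bumps; for propagating archetypes the body-row peak time
    increases linearly with the row index.
    """
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    a = archetype
    scale = sampling_rate / FS
    length = int(round(a.length * scale))
    t = np.arange(length) / scale
    base = baseline_pressures(spec or SimSpec())
    m = np.tile(base[:, None], (1, length)).astype(float)

    if a.name == "artifact":
        spike = a.amplitude * np.exp(-0.5 * ((t - a.onset) / a.sigma_t) ** 2)
        m += spike[None, :]
        return m, 0

    # UES relaxation marks the annotated swallow start
    ues_dip = a.ues_depth * np.exp(-0.5 * ((t - a.ues_center) / a.ues_sigma) ** 2)
    m[UES_ROWS] -= ues_dip[None, :]
    # LES relaxation across the swallow
    les_dip = a.les_depth * np.exp(-0.5 * ((t - a.les_center) / a.les_sigma) ** 2)
    m[LES_ROWS] -= les_dip[None, :]
    # body contraction
    rows = np.arange(BODY_ROWS.start, BODY_ROWS.stop)
    centers = a.onset + (rows - BODY_ROWS.start) * a.row_delay
    bump = a.amplitude * np.exp(
        -0.5 * ((t[None, :] - centers[:, None]) / a.sigma_t) ** 2
    )
    m[BODY_ROWS] += bump
    return m, 0


def _event_positions(
    n: int, t: int, min_gap: int, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """n starts in [lo, hi) with pairwise separation >= min_gap."""
    usable = hi - lo - (n - 1) * min_gap
    if n < 1 or usable < 0:
        raise ValueError(
            f"cannot place {n} events with min gap {min_gap} in [{lo}, {hi})"
        )
    offsets = np.sort(rng.uniform(0, usable, size=n))
    return (lo + offsets + np.arange(n) * min_gap).astype(np.int64)


def generate_recording(
    spec: SimSpec,
    patient_id: str = "p00",
    seed: int | None = None,
) -> tuple[ManometryRecording, AnnotationSet, list[tuple[int, str]]]:
    """One synthetic recording, its annotations and the event labels.

    Returns ``(recording, annotations, events)`` where ``events`` lists
    ``(start_index, archetype_name)`` for every inserted event, swallows
    and artifacts alike; only swallows appear in the annotations.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t = spec.t
    base = baseline_pressures(spec)
    m = np.tile(base[:, None], (1, t)).astype(float)

    n_swallows = int(round(spec.recording_minutes * spec.swallows_per_minute))
    hi = t - spec.end_margin - SWALLOW_LEN
    if n_swallows:
        starts = _event_positions(
            n_swallows, t, spec.min_gap, spec.start_margin, hi, rng
        )
    else:
        starts = np.array([], dtype=np.int64)
    names = list(spec.archetype_mixture)
    probs = np.array([spec.archetype_mixture[k] for k in names])
    kinds = rng.choice(names, size=n_swallows, p=probs)

    events: list[tuple[int, str]] = []
    for s, kind in zip(starts, kinds):
        patch, _ = render_swallow(kind, spec=spec)
        m[:, s : s + patch.shape[1]] += patch - base[:, None]
        events.append((int(s), str(kind)))

    # artifacts: rejection-sampled into gaps, kept clear of swallows
    n_art = int(round(spec.recording_minutes * spec.artifacts_per_minute))
    art_starts: list[int] = []
    guard = 300
    for _ in range(n_art):
        for _attempt in range(200):
            pos = int(rng.integers(spec.start_margin, t - ARTIFACT_LEN - 100))
            clear_sw = np.all(
                (pos + ARTIFACT_LEN + guard <= starts)
                | (pos >= starts + SWALLOW_LEN + guard)
            )
            clear_art = all(
                abs(pos - p) >= ARTIFACT_LEN + guard for p in art_starts
            )
            if clear_sw and clear_art:
                art_starts.append(pos)
                break
    for pos in art_starts:
        patch, _ = render_swallow("artifact", spec=spec)
        m[:, pos : pos + patch.shape[1]] += patch - base[:, None]
        events.append((pos, "artifact"))

    if spec.noise_sd > 0:
        m += rng.normal(0.0, spec.noise_sd, size=m.shape)

    events.sort()
    rec = ManometryRecording(patient_id=patient_id, pressures=m, sampling_rate_hz=FS)
    ann = AnnotationSet(patient_id=patient_id, starts=starts)
    return rec, ann, events


def generate_cohort(
    spec: SimSpec, seed: int | None = None
) -> tuple[list[ManometryRecording], list[AnnotationSet], list[list[tuple[int, str]]]]:
    """A cohort of ``spec.n_patients`` independent recordings.

    Per-patient seeds are spawned from the cohort seed, so any one patient
    is reproducible independently of the others.
    """
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(spec.n_patients)]
    recs, anns, labels = [], [], []
    for i, child in enumerate(child_seeds):
        pid = f"p{i + 1:02d}"
        rec, ann, events = generate_recording(spec, patient_id=pid, seed=child)
        recs.append(rec)
        anns.append(ann)
        labels.append(events)
    return recs, anns, labels


def events_per_24h(spec: SimSpec) -> float:
    """Swallow count extrapolated to a 24-hour recording."""
    return spec.swallows_per_minute * 60 * 24
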