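"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the inputs the analysis modules consume:

* photometry sessions — a calcium transient (double-exponential
  rise/decay kernel, a standard GCaMP phenomenology) riding on a slowly
  bleaching baseline, with optional motion artifacts injected with the
  same fractional magnitude into both channels so the 405 nm screen is
  exercised as designed;
* bottle-weight recordings — a start weight minus linearly consumed
  meal mass, evaporation drift, gaussian scale jitter, and optional
  transient positive bumps (animal contacting the bottle);
* cell-count tables — per-section multinomial draws from known class
  probabilities.

Every generator is deterministic given its seed and returns the ground
truth alongside the data, so recovery can be asserted exactly at zero
noise and within stated tolerances at default noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .meals import Meal, ScaleRecording, _consumed_by
from .photometry import PhotometrySession

__all__ = [
    "PhotometrySimConfig",
    "FeedingSimConfig",
    "CellSimConfig",
    "PhotometryGroundTruth",
    "FeedingGroundTruth",
    "CellGroundTruth",
    "gen_photometry_session",
    "gen_photometry_dataset",
    "gen_scale_recording",
    "gen_cell_counts",
    "write_ground_truth",
    "read_ground_truth",
]

# Default class probabilities for the two-marker co-expression table
# (inclusive-convention split of a nearly distinct two-population mix).
DEFAULT_CLASS_PROBS = {"tac1_only": 0.832, "crh_only": 0.149, "both": 0.019}


@dataclass
class PhotometrySimConfig:
    """Conditions for simulated two-channel photometry trials.

    Amplitude is the peak dF/F of an instantaneous-rise transient;
    ``noise_sd`` is the white-noise standard deviation as a fraction of
    each channel's baseline; the artifact is a shared fractional
    excursion of both channels lasting ``artifact_duration_s``.
    """

    n_trials: int = 6
    fs_hz: float = 20.0
    baseline_s: float = 60.0
    duration_s: float = 120.0
    amplitude: float = 0.3
    rise_tau_s: float = 0.0
    decay_tau_s: float = 20.0
    onset_s: float = 0.0
    bleach_rate_per_s: float = 5e-5
    noise_sd: float = 0.01
    artifact_prob: float = 0.0
    artifact_magnitude: float = 0.25
    artifact_duration_s: float = 3.0
    f0_465: float = 100.0
    f0_405: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.baseline_s <= 0 or self.duration_s <= 0:
            raise ValueError("rates and window lengths must be positive")
        for name in (
            "rise_tau_s",
            "decay_tau_s",
            "bleach_rate_per_s",
            "noise_sd",
            "artifact_prob",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PhotometryGroundTruth:
    """True transient and artifact parameters of one simulated trial."""

    subject_id: str
    trial_id: str
    amplitude: float
    rise_tau_s: float
    decay_tau_s: float
    onset_s: float
    artifact_time_s: float | None
    artifact_magnitude: float | None


@dataclass
class FeedingSimConfig:
    """Conditions for simulated bottle-weight recordings.

    Meals are (start_s, size_g, duration_s) triples; if None, a random
    non-overlapping schedule is drawn with the stated size/duration
    ranges and a minimum inter-meal gap.
    """

    session_s: float = 10800.0
    sample_interval_s: float = 1.0
    start_weight_g: float = 50.0
    meals: tuple[tuple[float, float, float], ...] | None = None
    n_meals: int = 5
    size_range_g: tuple[float, float] = (0.05, 0.5)
    duration_range_s: tuple[float, float] = (10.0, 60.0)
    min_gap_s: float = 30.0
    drift_g_per_h: float = 0.0
    noise_sd_g: float = 0.001
    bump_prob_per_s: float = 0.0
    bump_g: float = 0.05
    bump_duration_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_s <= 0 or self.sample_interval_s <= 0:
            raise ValueError("session_s and sample_interval_s must be positive")
        if self.noise_sd_g < 0 or self.bump_prob_per_s < 0 or self.drift_g_per_h < 0:
            raise ValueError("noise, bump and drift rates must be non-negative")


@dataclass
class FeedingGroundTruth:
    """True meal schedule of one simulated session."""

    subject_id: str
    session_id: str
    meals: list[dict] = field(default_factory=list)

    def as_meals(self) -> list[Meal]:
        return [
            Meal(
                start_s=m["start_s"],
                end_s=m["start_s"] + m["duration_s"],
                size_g=m["size_g"],
                duration_s=m["duration_s"],
            )
            for m in self.meals
        ]


@dataclass
class CellSimConfig:
    """Conditions for simulated per-section marker-class counts."""

    probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    n_animals: int = 4
    n_sections: int = 18
    cells_per_section: int = 100
    poisson_cells: bool = True
    bregma_range_mm: tuple[float, float] = (-2.3, -2.84)
    seed: int = 0


@dataclass
class CellGroundTruth:
    """True class probabilities behind a simulated count table."""

    probs: dict[str, float]
    n_animals: int
    n_sections: int


def _transient_kernel(
    t: np.ndarray, amplitude: float, rise_tau_s: float, decay_tau_s: float, onset_s: float
) -> np.ndarray:
    """Double-exponential transient; instantaneous rise when rise_tau_s == 0."""
    rel = t - onset_s
    out = np.zeros_like(t)
    pos = rel >= 0
    decay = (
        np.exp(-rel[pos] / decay_tau_s) if decay_tau_s > 0 else np.ones(pos.sum())
    )
    if rise_tau_s > 0:
        out[pos] = amplitude * (1.0 - np.exp(-rel[pos] / rise_tau_s)) * decay
    else:
        out[pos] = amplitude * decay
    return out


def gen_photometry_session(
    cfg: PhotometrySimConfig,
    subject_id: str = "sim",
    trial_id: str = "t000",
    rng: np.random.Generator | None = None,
) -> tuple[PhotometrySession, PhotometryGroundTruth]:
    """Simulate one two-channel trial with the event at t = 0.

    signal_465 = F0 * bleach(t) * (1 + transient(t)) * artifact(t) + noise
    signal_405 = F0' * bleach(t) * artifact(t) + noise

    The artifact multiplies both channels identically, mimicking shared
    motion; noise is i.i.d. gaussian per channel.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_pre = int(round(cfg.baseline_s * cfg.fs_hz))
    n_post = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(-n_pre, n_post) / cfg.fs_hz
    transient = _transient_kernel(
        t, cfg.amplitude, cfg.rise_tau_s, cfg.decay_tau_s, cfg.onset_s
    )
    bleach = np.exp(-cfg.bleach_rate_per_s * (t - t[0]))

    artifact_mult = np.ones_like(t)
    artifact_time: float | None = None
    if rng.random() < cfg.artifact_prob:
        # keep the excursion inside the post-event window, clear of edges
        hi = max(6.0, cfg.duration_s - cfg.artifact_duration_s - 5.0)
        artifact_time = float(np.floor(rng.uniform(5.0, hi)))
        mask = (t >= artifact_time) & (t < artifact_time + cfg.artifact_duration_s)
        artifact_mult[mask] = 1.0 + cfg.artifact_magnitude
    s465 = cfg.f0_465 * bleach * (1.0 + transient) * artifact_mult
    s405 = cfg.f0_405 * bleach * artifact_mult
    if cfg.noise_sd > 0:
        s465 = s465 + rng.normal(0.0, cfg.noise_sd * cfg.f0_465, t.size)
        s405 = s405 + rng.normal(0.0, cfg.noise_sd * cfg.f0_405, t.size)
    session = PhotometrySession(
        subject_id=subject_id,
        trial_id=trial_id,
        time_s=t,
        signal_465=s465,
        signal_405=s405,
        sample_rate_hz=cfg.fs_hz,
    )
    truth = PhotometryGroundTruth(
        subject_id=subject_id,
        trial_id=trial_id,
        amplitude=cfg.amplitude,
        rise_tau_s=cfg.rise_tau_s,
        decay_tau_s=cfg.decay_tau_s,
        onset_s=cfg.onset_s,
        artifact_time_s=artifact_time,
        artifact_magnitude=cfg.artifact_magnitude if artifact_time is not None else None,
    )
    return session, truth


def gen_photometry_dataset(
    cfg: PhotometrySimConfig,
) -> tuple[list[PhotometrySession], list[PhotometryGroundTruth]]:
    """Simulate ``cfg.n_trials`` trials, one subject per trial."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trials)
    sessions, truths = [], []
    for i, ss in enumerate(seeds):
        session, truth = gen_photometry_session(
            cfg,
            subject_id=f"m{i + 1:02d}",
            trial_id=f"t{i:03d}",
            rng=np.random.default_rng(ss),
        )
        sessions.append(session)
        truths.append(truth)
    return sessions, truths


def gen_scale_recording(
    cfg: FeedingSimConfig,
    subject_id: str = "sim",
    session_id: str = "s000",
    rng: np.random.Generator | None = None,
) -> tuple[ScaleRecording, FeedingGroundTruth]:
    """Simulate one bottle-weight recording with a known meal schedule."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.meals is not None:
        schedule = [tuple(map(float, m)) for m in cfg.meals]
    else:
        schedule = _random_meal_schedule(cfg, rng)
    schedule.sort()
    for (s0, _, d0), (s1, _, _) in zip(schedule, schedule[1:]):
        if s0 + d0 > s1:
            raise ValueError("overlapping meals in schedule")
    for s, size, d in schedule:
        if size <= 0 or d < 0:
            raise ValueError("meal sizes must be positive and durations non-negative")
        if s < 0 or s + d > cfg.session_s:
            raise ValueError("meals must fit inside the session")

    t = np.arange(0.0, cfg.session_s, cfg.sample_interval_s)
    meals = [
        Meal(start_s=s, end_s=s + max(d, 1e-9), size_g=size, duration_s=max(d, 1e-9))
        for s, size, d in schedule
    ]
    weight = cfg.start_weight_g - _consumed_by(meals, t)
    weight = weight - cfg.drift_g_per_h * t / 3600.0
    if cfg.bump_prob_per_s > 0:
        p = cfg.bump_prob_per_s * cfg.sample_interval_s
        starts = np.nonzero(rng.random(t.size) < p)[0]
        bump = np.zeros_like(t)
        width = max(1, int(round(cfg.bump_duration_s / cfg.sample_interval_s)))
        for i in starts:
            bump[i : i + width] += cfg.bump_g
        weight = weight + bump
    if cfg.noise_sd_g > 0:
        weight = weight + rng.normal(0.0, cfg.noise_sd_g, t.size)
    weight = np.maximum(weight, 0.0)
    rec = ScaleRecording(
        subject_id=subject_id, session_id=session_id, time_s=t, weight_g=weight
    )
    truth = FeedingGroundTruth(
        subject_id=subject_id,
        session_id=session_id,
        meals=[
            {"start_s": s, "size_g": size, "duration_s": d} for s, size, d in schedule
        ],
    )
    return rec, truth


def _random_meal_schedule(
    cfg: FeedingSimConfig, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Draw a non-overlapping meal schedule with gaps >= cfg.min_gap_s."""
    sizes = rng.uniform(*cfg.size_range_g, cfg.n_meals)
    durations = rng.uniform(*cfg.duration_range_s, cfg.n_meals)
    busy = float(np.sum(durations)) + cfg.min_gap_s * (cfg.n_meals + 1)
    slack = cfg.session_s - busy
    if slack < 0:
        raise ValueError("meals do not fit in the session with the required gaps")
    # distribute the free time as random extra gaps
    extra = rng.uniform(0.0, 1.0, cfg.n_meals + 1)
    extra = extra / extra.sum() * slack
    schedule = []
    clock = cfg.min_gap_s + extra[0]
    for i in range(cfg.n_meals):
        schedule.append((float(clock), float(sizes[i]), float(durations[i])))
        clock += durations[i] + cfg.min_gap_s + extra[i + 1]
    return schedule


def gen_cell_counts(
    cfg: CellSimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, CellGroundTruth]:
    """Simulate a long-format count table by per-section multinomial draws."""
    probs = dict(cfg.probs)
    values = np.array(list(probs.values()), dtype=float)
    if np.any(values < 0) or abs(values.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must be non-negative and sum to 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    classes = list(probs.keys())
    bregma = np.linspace(*cfg.bregma_range_mm, cfg.n_sections)
    rows = []
    for a in range(cfg.n_animals):
        animal = f"a{a + 1:02d}"
        for s in range(cfg.n_sections):
            n_cells = (
                int(rng.poisson(cfg.cells_per_section))
                if cfg.poisson_cells
                else cfg.cells_per_section
            )
            draws = rng.multinomial(n_cells, values)
            for cls, count in zip(classes, draws):
                rows.append(
                    {
                        "animal_id": animal,
                        "section_id": f"s{s + 1:02d}",
                        "bregma_mm": round(float(bregma[s]), 4),
                        "class": cls,
                        "count": int(count),
                    }
                )
    table = pd.DataFrame(rows)
    truth = CellGroundTruth(
        probs=probs, n_animals=cfg.n_animals, n_sections=cfg.n_sections
    )
    return table, truth


def write_ground_truth(truth, path: str | Path) -> None:
    """Serialize a ground-truth record (or list of records) to JSON."""
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        raise TypeError(f"cannot serialize {type(obj)!r}")

    Path(path).write_text(json.dumps(truth, default=encode, indent=2, sort_keys=True))


def read_ground_truth(path: str | Path):
    """Load a ground-truth JSON file written by :func:`write_ground_truth`."""
    return json.loads(Path(path).read_text())
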