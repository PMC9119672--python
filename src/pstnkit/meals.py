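"""Meal-microstructure analysis of continuous bottle-weight recordings.

A scale under the liquid-diet bottle is sampled continuously; feeding
bouts appear as decreasing spans of the weight trace. A meal is any net
weight decrease strictly greater than a size threshold (default 0.02 g),
with bouts separated by less than a merge gap (default 15 s) counted as
a single meal. Detected meals feed microstructure statistics (size,
duration, frequency), cumulative-intake curves, and per-epoch totals
for pre/stimulation/post designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScaleRecording",
    "Meal",
    "MealStats",
    "IntakeCurve",
    "detect_meals",
    "meal_statistics",
    "cumulative_intake",
    "epoch_totals",
    "per_subject_session_mean",
    "grams_to_kcal",
]

#: A net drop must strictly exceed this many grams to count as a meal.
DEFAULT_MIN_MEAL_G = 0.02
#: Bouts separated by less than this many seconds merge into one meal.
DEFAULT_MERGE_GAP_S = 15.0
#: Upward fluctuation tolerated within a bout (scale jitter), grams.
DEFAULT_NOISE_TOL_G = 0.005
#: Caloric density of the 1:1-diluted liquid diet, kcal per liter.
KCAL_PER_L = 450.0


@dataclass
class ScaleRecording:
    """Continuous bottle-weight trace for one session."""

    subject_id: str
    session_id: str
    time_s: np.ndarray
    weight_g: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.weight_g = np.asarray(self.weight_g, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size != self.weight_g.size:
            raise ValueError("time_s and weight_g must be 1-D and equally long")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if not (np.all(np.isfinite(self.time_s)) and np.all(np.isfinite(self.weight_g))):
            raise ValueError("times and weights must be finite")
        if np.any(self.weight_g < 0):
            raise ValueError("weights must be non-negative")


@dataclass
class Meal:
    """One detected feeding bout."""

    start_s: float
    end_s: float
    size_g: float
    duration_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("meal must end after it starts")
        if abs(self.duration_s - (self.end_s - self.start_s)) > 1e-9:
            raise ValueError("duration_s must equal end_s - start_s")
        if not self.size_g > 0:
            raise ValueError("meal size must be positive")


@dataclass
class MealStats:
    """Microstructure statistics over meals starting inside a window.

    Means are NaN when no meals fall inside the window.
    """

    n_meals: int
    mean_size_g: float
    mean_duration_s: float
    frequency_per_h: float
    total_intake_g: float


@dataclass
class IntakeCurve:
    """Cumulative grams consumed at each bin edge, non-decreasing."""

    bin_edges_s: np.ndarray
    cumulative_g: np.ndarray


def _candidate_bouts(
    t: np.ndarray, w: np.ndarray, noise_tol_g: float, max_flat_s: float
) -> list[tuple[int, int]]:
    """Maximal decreasing spans as (start_index, end_index) pairs.

    The trace is read through a dead band of half-width
    ``noise_tol_g``: the weight registers a movement only when it
    differs from the last committed level by more than the tolerance,
    so scale jitter inside the band produces no movements at all. A
    bout starts at the sample preceding a committed downward movement
    and chains further downward movements; it ends when the weight
    commits an upward movement or stays inside the band for
    ``max_flat_s`` seconds after the last downward movement (feeding
    stopped). With ``noise_tol_g = 0`` every strict sample-to-sample
    decrease is a movement and spans are exact. The end index is the
    last committed downward movement, so each bout's start/end weights
    bracket the true levels within one tolerance each.
    """
    bouts: list[tuple[int, int]] = []
    n = w.size
    anchor = w[0]
    in_bout = False
    start = end = 0
    last_down_t = 0.0
    for i in range(1, n):
        d = w[i] - anchor
        if d < -noise_tol_g:
            anchor = w[i]
            if not in_bout:
                in_bout = True
                start = i - 1
            end = i
            last_down_t = t[i]
        elif d > noise_tol_g:
            anchor = w[i]
            if in_bout:
                bouts.append((start, end))
                in_bout = False
        elif in_bout and t[i] - last_down_t >= max_flat_s:
            bouts.append((start, end))
            in_bout = False
    if in_bout:
        bouts.append((start, end))
    return bouts


def detect_meals(
    rec: ScaleRecording,
    min_meal_g: float = DEFAULT_MIN_MEAL_G,
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
    noise_tol_g: float = DEFAULT_NOISE_TOL_G,
) -> list[Meal]:
    """Detect meals from a bottle-weight trace.

    Three stages: (1) find maximal decreasing spans, reading the trace
    through a dead band of half-width ``noise_tol_g`` so jitter inside
    the band neither starts, extends, nor ends a span, and ending a
    span once the weight has been flat for ``merge_gap_s`` (feeding
    stopped); (2) merge bouts
    whose gap (next start minus previous end) is strictly less than
    ``merge_gap_s`` — a gap of exactly ``merge_gap_s`` separates two
    meals — with the merged size being the total drop from the merged
    start to the merged end; (3) discard meals whose size does not
    strictly exceed ``min_meal_g``. Filtering happens after merging, so
    nearby sub-threshold drops can jointly form a meal. Returned sorted
    by start time, non-overlapping.
    """
    if noise_tol_g < 0:
        raise ValueError("noise_tol_g must be non-negative")
    if min_meal_g < 0 or merge_gap_s < 0:
        raise ValueError("min_meal_g and merge_gap_s must be non-negative")
    if rec.time_s.size < 2:
        raise ValueError("recording needs at least 2 samples")
    t = rec.time_s
    w = rec.weight_g

    bouts = _candidate_bouts(t, w, noise_tol_g, max_flat_s=merge_gap_s)

    merged: list[tuple[int, int]] = []
    for s, e in bouts:
        if merged and t[s] - t[merged[-1][1]] < merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    meals: list[Meal] = []
    for s, e in merged:
        size = float(w[s] - w[e])
        if size > min_meal_g:
            meals.append(
                Meal(
                    start_s=float(t[s]),
                    end_s=float(t[e]),
                    size_g=size,
                    duration_s=float(t[e] - t[s]),
                )
            )
    return meals


def meal_statistics(meals: list[Meal], window: tuple[float, float]) -> MealStats:
    """Statistics over meals whose start falls inside [window[0], window[1])."""
    lo, hi = window
    if not hi > lo:
        raise ValueError("window length must be positive")
    inside = [m for m in meals if lo <= m.start_s < hi]
    n = len(inside)
    window_h = (hi - lo) / 3600.0
    if n == 0:
        return MealStats(0, math.nan, math.nan, 0.0, 0.0)
    sizes = [m.size_g for m in inside]
    durations = [m.duration_s for m in inside]
    return MealStats(
        n_meals=n,
        mean_size_g=float(np.mean(sizes)),
        mean_duration_s=float(np.mean(durations)),
        frequency_per_h=n / window_h,
        total_intake_g=float(np.sum(sizes)),
    )


def _consumed_by(meals: list[Meal], t: np.ndarray) -> np.ndarray:
    """Grams consumed up to each time, attributing mass linearly in time
    within each meal (step attribution for zero-duration meals)."""
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    for m in meals:
        if m.duration_s > 0:
            frac = np.clip((t - m.start_s) / m.duration_s, 0.0, 1.0)
        else:
            frac = (t >= m.start_s).astype(float)
        total += m.size_g * frac
    return total


def cumulative_intake(
    meals: list[Meal], bin_s: float, window: tuple[float, float]
) -> IntakeCurve:
    """Cumulative intake at bin edges spanning the window.

    Each meal's mass accrues linearly across its duration; the curve is
    referenced to the window start, so the final value is the total
    mass consumed during the window (including the in-window share of
    straddling meals).
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    lo, hi = window
    if not hi > lo:
        raise ValueError("window length must be positive")
    n_bins = int(math.ceil((hi - lo) / bin_s - 1e-12))
    edges = lo + bin_s * np.arange(n_bins + 1)
    if edges[-1] > hi:
        edges[-1] = hi
    consumed = _consumed_by(meals, edges)
    cumulative = consumed - consumed[0]
    return IntakeCurve(bin_edges_s=edges, cumulative_g=cumulative)


def epoch_totals(
    meals: list[Meal], epochs: list[tuple[float, float]]
) -> list[float]:
    """Grams consumed per epoch (e.g. 1 h pre / stimulation / post).

    Epochs must be non-overlapping; meal mass is attributed linearly
    over the meal's duration, so a meal straddling an epoch boundary is
    split in proportion to the time spent in each epoch.
    """
    eps = sorted(epochs)
    for lo, hi in eps:
        if not hi > lo:
            raise ValueError("epoch length must be positive")
    for (_, a1), (b0, _) in zip(eps, eps[1:]):
        if a1 > b0:
            raise ValueError("overlapping epochs")
    totals = []
    for lo, hi in epochs:
        total = 0.0
        for m in meals:
            if m.duration_s > 0:
                overlap = max(0.0, min(hi, m.end_s) - max(lo, m.start_s))
                total += m.size_g * overlap / m.duration_s
            elif lo <= m.start_s < hi:
                total += m.size_g
        totals.append(total)
    return totals


def per_subject_session_mean(
    session_values: dict[str, list[float]]
) -> dict[str, float]:
    """Arithmetic mean of per-session totals for each subject.

    Mirrors designs where each animal runs several sessions and the
    per-animal mean is the unit of analysis.
    """
    means: dict[str, float] = {}
    for subject, values in session_values.items():
        if len(values) == 0:
            raise ValueError(f"subject {subject!r} has no sessions")
        means[subject] = float(np.mean(values))
    return means


def grams_to_kcal(
    grams: float, kcal_per_l: float = KCAL_PER_L, density_g_per_ml: float = 1.0
) -> float:
    """Convert grams of liquid diet to kcal (default 450 kcal/L, 1 g/mL)."""
    if density_g_per_ml <= 0:
        raise ValueError("density must be positive")
    return grams / density_g_per_ml / 1000.0 * kcal_per_l
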