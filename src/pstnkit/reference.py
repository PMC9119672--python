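"""Enumeration-based reference meal detector.

A deliberately stateless re-derivation of the meal definition used to
validate :func:`pstnkit.meals.detect_meals`. The committed weight
movements are derived first as an explicit event list, bouts are then
assembled from the event list declaratively, and merging and size
filtering are applied as separate explicit passes. Intended for small
traces and equivalence testing, not production use.
"""

from __future__ import annotations

import numpy as np

from .meals import Meal, ScaleRecording

__all__ = ["brute_force_detect_meals"]


def _movement_events(w: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Committed movements as (index, direction) with direction +/-1.

    A movement is the first sample differing from the previously
    committed level by more than ``tol``; the committed level then
    jumps to that sample (dead-band reading of the trace).
    """
    events: list[tuple[int, int]] = []
    level_idx = 0
    while True:
        beyond = np.nonzero(np.abs(w[level_idx + 1 :] - w[level_idx]) > tol)[0]
        if beyond.size == 0:
            return events
        i = level_idx + 1 + int(beyond[0])
        events.append((i, -1 if w[i] < w[level_idx] else +1))
        level_idx = i


def brute_force_detect_meals(
    rec: ScaleRecording,
    min_meal_g: float = 0.02,
    merge_gap_s: float = 15.0,
    noise_tol_g: float = 0.005,
) -> list[Meal]:
    """Detect meals by explicit event enumeration, merge, then filter.

    Semantics: with the trace read through a dead band of half-width
    ``noise_tol_g``, a bout is a maximal run of downward movements not
    interrupted by an upward movement, where each next downward
    movement arrives before any intermediate sample sits a full
    ``merge_gap_s`` after the previous one (that much flatness ends
    the bout). The bout spans from the sample preceding its first
    downward movement to its last downward movement. Bouts with gaps
    < ``merge_gap_s`` (end-of-previous to start-of-next) are merged;
    merged size is the total drop from the merged start to the merged
    end. Meals must strictly exceed ``min_meal_g``.
    """
    if noise_tol_g < 0:
        raise ValueError("noise_tol_g must be non-negative")
    t = np.asarray(rec.time_s, dtype=float)
    w = np.asarray(rec.weight_g, dtype=float)

    # stage 1: bouts from the committed-movement event list
    events = _movement_events(w, noise_tol_g)
    bouts: list[tuple[int, int]] = []
    start = end = None
    for idx, direction in events:
        if direction < 0:
            if start is not None and idx > end + 1 and t[idx - 1] - t[end] >= merge_gap_s:
                # an intermediate flat sample already closed the bout
                bouts.append((start, end))
                start = None
            if start is None:
                start = idx - 1
            end = idx
        else:
            if start is not None:
                bouts.append((start, end))
                start = None
    if start is not None:
        bouts.append((start, end))

    # stage 2: merge bouts closer than the gap
    merged: list[tuple[int, int]] = []
    for s, e in bouts:
        if merged and t[s] - t[merged[-1][1]] < merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    # stage 3: strict size filter
    meals = []
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
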