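"""Event-aligned fiber-photometry processing.

A recording consists of two demodulated fluorescence channels: a 465 nm
calcium-dependent GCaMP signal and a 405 nm calcium-independent control.
The pipeline reduces both channels to 1 Hz by bin averaging, normalizes
the signal channel to the median of a pre-event baseline window
(dF/F = (F - F_baseline) / F_baseline), excludes trials whose control
channel deviates from its own baseline median by more than a fractional
threshold (motion/bleaching artifacts), and summarizes the response with
a peak value over a post-event window and the area under the curve up to
the first return to zero.

Time is expressed in seconds relative to the stimulus event at t = 0;
negative times are baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhotometrySession",
    "DffTrace",
    "TraceMetrics",
    "GroupTraceSummary",
    "downsample_1hz",
    "compute_dff",
    "qc_artifact_flag",
    "process_session",
    "max_dff",
    "auc_to_zero",
    "trace_metrics",
    "summarize_group",
]

#: Default length of the pre-event window whose median defines F_baseline.
DEFAULT_BASELINE_S = 30.0
#: Default fractional 405 nm deviation above which a trial is excluded.
DEFAULT_QC_THRESHOLD = 0.20
#: Default post-event window for the peak dF/F metric.
DEFAULT_MAX_WINDOW_S = (0.0, 75.0)


@dataclass
class PhotometrySession:
    """Raw (or already downsampled) two-channel recording for one trial."""

    subject_id: str
    trial_id: str
    time_s: np.ndarray
    signal_465: np.ndarray
    signal_405: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal_465 = np.asarray(self.signal_465, dtype=float)
        self.signal_405 = np.asarray(self.signal_405, dtype=float)
        n = self.time_s.size
        if self.time_s.ndim != 1 or self.signal_465.size != n or self.signal_405.size != n:
            raise ValueError("time_s, signal_465 and signal_405 must be 1-D and equally long")
        if n == 0:
            raise ValueError("empty recording")
        if n >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if not (
            np.all(np.isfinite(self.time_s))
            and np.all(np.isfinite(self.signal_465))
            and np.all(np.isfinite(self.signal_405))
        ):
            raise ValueError("times and signals must be finite")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class DffTrace:
    """Baseline-normalized dF/F series for one trial.

    ``qc_excluded`` marks trials rejected by the 405 nm artifact screen;
    metric functions refuse excluded traces.
    """

    subject_id: str
    trial_id: str
    time_s: np.ndarray
    dff: np.ndarray
    f_baseline: float
    qc_excluded: bool = False
    qc_reason: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.time_s.size != self.dff.size:
            raise ValueError("time_s and dff must be equally long")
        if not self.f_baseline > 0:
            raise ValueError("f_baseline must be positive")


@dataclass
class TraceMetrics:
    """Per-trial response metrics.

    ``t_return_s`` is None when dF/F never returns to zero within the
    recording (serialized as ``"never"``).
    """

    max_dff: float
    auc: float
    t_return_s: float | None


@dataclass
class GroupTraceSummary:
    """Across-trial mean +/- SEM and the per-trial heat-map matrix."""

    time_s: np.ndarray
    mean_dff: np.ndarray
    sem_dff: np.ndarray
    heatmap: np.ndarray  # trials x time
    subject_ids: list[str] = field(default_factory=list)
    trial_ids: list[str] = field(default_factory=list)
    n_excluded: int = 0
    excluded: list[tuple[str, str, str]] = field(default_factory=list)
    sem_undefined: bool = False  # True when only one trial contributed


def _baseline_mask(time_s: np.ndarray, baseline_s: float) -> np.ndarray:
    """Samples in the pre-event window [-baseline_s, 0)."""
    return (time_s >= -baseline_s) & (time_s < 0.0)


def downsample_1hz(session: PhotometrySession) -> PhotometrySession:
    """Reduce both channels to 1 Hz by averaging 1 s bins.

    Bins are the intervals [k, k+1) seconds, so one bin edge always
    falls on the event at t = 0 and no bin straddles it. Each output
    sample carries the integer second label k of its bin. The two
    channels are averaged independently with identical binning.
    """
    if session.sample_rate_hz < 1.0:
        raise ValueError("cannot downsample upward: sample rate below 1 Hz")
    if session.duration_s + 1.0 / session.sample_rate_hz < 2.0:
        raise ValueError("recording must cover at least 2 s to downsample")
    bins = np.floor(session.time_s).astype(np.int64)
    labels, starts = np.unique(bins, return_index=True)
    counts = np.diff(np.append(starts, bins.size))
    m465 = np.add.reduceat(session.signal_465, starts) / counts
    m405 = np.add.reduceat(session.signal_405, starts) / counts
    return PhotometrySession(
        subject_id=session.subject_id,
        trial_id=session.trial_id,
        time_s=labels.astype(float),
        signal_465=m465,
        signal_405=m405,
        sample_rate_hz=1.0,
    )


def compute_dff(
    session: PhotometrySession, baseline_s: float = DEFAULT_BASELINE_S
) -> DffTrace:
    """Normalize the 465 nm channel to its pre-event baseline median.

    dF/F(t) = (F(t) - F_baseline) / F_baseline with F_baseline the
    median of the 465 nm samples in [-baseline_s, 0). No isosbestic
    regression is applied; the 405 nm channel is used only for the
    artifact screen (:func:`qc_artifact_flag`).
    """
    if baseline_s <= 0:
        raise ValueError("baseline_s must be positive")
    mask = _baseline_mask(session.time_s, baseline_s)
    if not mask.any() or session.time_s[0] > -baseline_s:
        raise ValueError(
            f"insufficient baseline: need samples covering {baseline_s:g} s before t=0"
        )
    f_baseline = float(np.median(session.signal_465[mask]))
    if f_baseline <= 0:
        raise ValueError("non-positive baseline")
    dff = (session.signal_465 - f_baseline) / f_baseline
    return DffTrace(
        subject_id=session.subject_id,
        trial_id=session.trial_id,
        time_s=session.time_s.copy(),
        dff=dff,
        f_baseline=f_baseline,
    )


def qc_artifact_flag(
    session: PhotometrySession,
    threshold: float = DEFAULT_QC_THRESHOLD,
    baseline_s: float = DEFAULT_BASELINE_S,
) -> tuple[bool, str]:
    """Screen a trial for motion/bleaching artifacts on the 405 nm channel.

    The trial is excluded iff the peak fractional deviation of the
    405 nm signal from its own baseline-window median strictly exceeds
    ``threshold`` anywhere in the recording. Returns ``(excluded,
    reason)``; the reason records the offending time and magnitude.
    """
    if session.signal_405.size == 0:
        raise ValueError("empty 405 nm channel")
    mask = _baseline_mask(session.time_s, baseline_s)
    if not mask.any():
        raise ValueError("no 405 nm baseline samples before t=0")
    b405 = float(np.median(session.signal_405[mask]))
    if b405 <= 0:
        raise ValueError("non-positive 405 nm baseline median")
    deviation = np.abs(session.signal_405 - b405) / b405
    i = int(np.argmax(deviation))
    peak = float(deviation[i])
    if peak > threshold:
        reason = (
            f"405 nm deviation {peak * 100:.1f}% at t={session.time_s[i]:.0f} s "
            f"exceeds {threshold * 100:.0f}% threshold"
        )
        return True, reason
    return False, ""


def process_session(
    session: PhotometrySession,
    baseline_s: float = DEFAULT_BASELINE_S,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> DffTrace:
    """Downsample to 1 Hz, normalize, and apply the artifact screen."""
    at_1hz = downsample_1hz(session)
    trace = compute_dff(at_1hz, baseline_s=baseline_s)
    excluded, reason = qc_artifact_flag(at_1hz, threshold=qc_threshold, baseline_s=baseline_s)
    trace.qc_excluded = excluded
    trace.qc_reason = reason
    return trace


def _require_analyzable(trace: DffTrace) -> None:
    if trace.qc_excluded:
        raise ValueError(
            f"trace {trace.subject_id}/{trace.trial_id} is QC-excluded: {trace.qc_reason}"
        )


def max_dff(
    trace: DffTrace, window_s: tuple[float, float] = DEFAULT_MAX_WINDOW_S
) -> float:
    """Peak dF/F over the closed post-event window [window_s[0], window_s[1]]."""
    _require_analyzable(trace)
    lo, hi = window_s
    mask = (trace.time_s >= lo) & (trace.time_s <= hi)
    if not mask.any():
        raise ValueError(f"no samples in analysis window [{lo:g}, {hi:g}] s")
    return float(np.max(trace.dff[mask]))


def auc_to_zero(trace: DffTrace) -> tuple[float, float | None]:
    """Trapezoidal area under dF/F from t=0 to the first return to zero.

    The onset sign is the sign of dF/F at the first sample strictly
    after t=0. For a positive onset the return time is the first sample
    time > 0 with dF/F <= 0 (symmetrically >= 0 for a negative onset);
    no interpolation of the crossing is applied. When the trace never
    returns to zero, the integral runs to the end of the recording and
    the return time is None ("never"). Degenerate traces (fewer than
    two post-event samples) yield an area of zero.
    """
    _require_analyzable(trace)
    mask = trace.time_s >= 0.0
    t = trace.time_s[mask]
    y = trace.dff[mask]
    post = t > 0.0
    if not post.any():
        return 0.0, None
    first = int(np.argmax(post))
    onset_sign = math.copysign(1.0, y[first]) if y[first] != 0.0 else 0.0
    if onset_sign == 0.0:
        end = first
    else:
        if onset_sign > 0:
            returned = post & (y <= 0.0)
        else:
            returned = post & (y >= 0.0)
        end = int(np.argmax(returned)) if returned.any() else None
    if end is None:
        auc = float(np.trapezoid(y, t)) if t.size >= 2 else 0.0
        return auc, None
    seg_t = t[: end + 1]
    seg_y = y[: end + 1]
    auc = float(np.trapezoid(seg_y, seg_t)) if seg_t.size >= 2 else 0.0
    return auc, float(t[end])


def trace_metrics(
    trace: DffTrace, window_s: tuple[float, float] = DEFAULT_MAX_WINDOW_S
) -> TraceMetrics:
    """Compute the peak and area-under-curve metrics for one trial."""
    peak = max_dff(trace, window_s=window_s)
    auc, t_return = auc_to_zero(trace)
    return TraceMetrics(max_dff=peak, auc=auc, t_return_s=t_return)


def summarize_group(traces: list[DffTrace]) -> GroupTraceSummary:
    """Across-trial mean +/- SEM on a shared time grid.

    QC-excluded traces are dropped (and reported in the summary); the
    remaining traces must share an identical time grid. Heat-map rows
    are ordered by (subject_id, trial_id). SEM uses the sample standard
    deviation over trials divided by sqrt(n); with a single trial the
    SEM is reported as zero and flagged undefined.
    """
    excluded = [
        (tr.subject_id, tr.trial_id, tr.qc_reason) for tr in traces if tr.qc_excluded
    ]
    kept = sorted(
        (tr for tr in traces if not tr.qc_excluded),
        key=lambda tr: (tr.subject_id, tr.trial_id),
    )
    if not kept:
        raise ValueError("no analyzable trials: all traces QC-excluded or none given")
    grid = kept[0].time_s
    for tr in kept[1:]:
        if tr.time_s.size != grid.size or not np.array_equal(tr.time_s, grid):
            raise ValueError("traces must share a common time grid")
    heatmap = np.vstack([tr.dff for tr in kept])
    n = heatmap.shape[0]
    mean = heatmap.mean(axis=0)
    if n > 1:
        sem = heatmap.std(axis=0, ddof=1) / math.sqrt(n)
        sem_undefined = False
    else:
        sem = np.zeros_like(mean)
        sem_undefined = True
    return GroupTraceSummary(
        time_s=grid.copy(),
        mean_dff=mean,
        sem_dff=sem,
        heatmap=heatmap,
        subject_ids=[tr.subject_id for tr in kept],
        trial_ids=[tr.trial_id for tr in kept],
        n_excluded=len(excluded),
        excluded=excluded,
        sem_undefined=sem_undefined,
    )
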