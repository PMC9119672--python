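"""Delimited-text input/output for all pipeline stages.

Photometry trials are one CSV per trial with columns
``time_s, signal_465, signal_405`` (header required; negative times are
baseline, the event is at t = 0). Bottle-weight sessions are CSVs with
``time_s, weight_g`` listed in a manifest. Cell counts are a single
long-format CSV. All writers use a fixed float format so identical
analyses produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cells import validate_cell_counts
from .meals import IntakeCurve, Meal, MealStats, ScaleRecording
from .photometry import DffTrace, GroupTraceSummary, PhotometrySession, TraceMetrics

__all__ = [
    "read_photometry_csv",
    "write_photometry_csv",
    "write_dff_csv",
    "write_metrics_csv",
    "write_group_summary_csv",
    "write_heatmap_csv",
    "read_scale_csv",
    "write_scale_csv",
    "read_manifest",
    "write_meals_csv",
    "write_meal_stats_csv",
    "write_intake_curve_csv",
    "read_cell_counts_csv",
]

FLOAT_FORMAT = "%.9g"

PHOTOMETRY_COLUMNS = ["time_s", "signal_465", "signal_405"]
SCALE_COLUMNS = ["time_s", "weight_g"]
MANIFEST_COLUMNS = ["subject_id", "session_id", "path"]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {missing}")


def _infer_rate(time_s: np.ndarray) -> float:
    if time_s.size < 2:
        raise ValueError("need at least 2 samples to infer a sample rate")
    return 1.0 / float(np.median(np.diff(time_s)))


def read_photometry_csv(
    path: str | Path, subject_id: str | None = None, trial_id: str | None = None
) -> PhotometrySession:
    """Read one trial; ids default to the file stem as ``subject`` and ``trial``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PHOTOMETRY_COLUMNS, f"photometry file {path.name}")
    t = df["time_s"].to_numpy(dtype=float)
    return PhotometrySession(
        subject_id=subject_id if subject_id is not None else path.stem,
        trial_id=trial_id if trial_id is not None else path.stem,
        time_s=t,
        signal_465=df["signal_465"].to_numpy(dtype=float),
        signal_405=df["signal_405"].to_numpy(dtype=float),
        sample_rate_hz=_infer_rate(t),
    )


def write_photometry_csv(session: PhotometrySession, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": session.time_s,
            "signal_465": session.signal_465,
            "signal_405": session.signal_405,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_dff_csv(trace: DffTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "dff": trace.dff}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_metrics_csv(
    rows: list[dict], path: str | Path
) -> None:
    """Write per-trial metrics; ``t_return_s`` of None is written as ``never``."""
    out = []
    for row in rows:
        row = dict(row)
        if row.get("t_return_s") is None:
            row["t_return_s"] = "never"
        out.append(row)
    columns = [
        "subject_id",
        "trial_id",
        "max_dff",
        "auc",
        "t_return_s",
        "qc_excluded",
        "qc_reason",
    ]
    pd.DataFrame(out, columns=columns).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def metrics_row(
    trace: DffTrace, metrics: TraceMetrics | None
) -> dict:
    """Assemble one metrics-CSV row; metrics is None for excluded trials."""
    return {
        "subject_id": trace.subject_id,
        "trial_id": trace.trial_id,
        "max_dff": metrics.max_dff if metrics else np.nan,
        "auc": metrics.auc if metrics else np.nan,
        "t_return_s": metrics.t_return_s if metrics else np.nan,
        "qc_excluded": trace.qc_excluded,
        "qc_reason": trace.qc_reason,
    }


def write_group_summary_csv(summary: GroupTraceSummary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": summary.time_s,
            "mean_dff": summary.mean_dff,
            "sem_dff": summary.sem_dff,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_heatmap_csv(summary: GroupTraceSummary, path: str | Path) -> None:
    """Trials x time matrix; rows labeled subject_id/trial_id."""
    df = pd.DataFrame(
        summary.heatmap,
        index=[f"{s}/{tr}" for s, tr in zip(summary.subject_ids, summary.trial_ids)],
        columns=[f"{t:g}" for t in summary.time_s],
    )
    df.index.name = "trial"
    df.to_csv(path, float_format=FLOAT_FORMAT)


def read_scale_csv(
    path: str | Path, subject_id: str | None = None, session_id: str | None = None
) -> ScaleRecording:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SCALE_COLUMNS, f"scale file {path.name}")
    return ScaleRecording(
        subject_id=subject_id if subject_id is not None else path.stem,
        session_id=session_id if session_id is not None else path.stem,
        time_s=df["time_s"].to_numpy(dtype=float),
        weight_g=df["weight_g"].to_numpy(dtype=float),
    )


def write_scale_csv(rec: ScaleRecording, path: str | Path) -> None:
    pd.DataFrame({"time_s": rec.time_s, "weight_g": rec.weight_g}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Session manifest: ``subject_id, session_id, path`` plus free columns."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, MANIFEST_COLUMNS, f"manifest {path.name}")
    return df


def write_meals_csv(
    meals_by_session: list[tuple[str, str, list[Meal]]], path: str | Path
) -> None:
    rows = [
        {
            "subject_id": subject,
            "session_id": session,
            "start_s": m.start_s,
            "end_s": m.end_s,
            "size_g": m.size_g,
            "duration_s": m.duration_s,
        }
        for subject, session, ms in meals_by_session
        for m in ms
    ]
    columns = ["subject_id", "session_id", "start_s", "end_s", "size_g", "duration_s"]
    pd.DataFrame(rows, columns=columns).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_meal_stats_csv(
    stats_by_session: list[tuple[str, str, MealStats]], path: str | Path
) -> None:
    rows = [
        {
            "subject_id": subject,
            "session_id": session,
            "n_meals": st.n_meals,
            "mean_size_g": st.mean_size_g,
            "mean_duration_s": st.mean_duration_s,
            "frequency_per_h": st.frequency_per_h,
            "total_intake_g": st.total_intake_g,
        }
        for subject, session, st in stats_by_session
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_intake_curve_csv(
    curves_by_session: list[tuple[str, str, IntakeCurve]], path: str | Path
) -> None:
    rows = [
        {
            "subject_id": subject,
            "session_id": session,
            "bin_edge_s": edge,
            "cumulative_g": value,
        }
        for subject, session, curve in curves_by_session
        for edge, value in zip(curve.bin_edges_s, curve.cumulative_g)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cell_counts_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cell-count table."""
    df = pd.read_csv(path)
    return validate_cell_counts(df)
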