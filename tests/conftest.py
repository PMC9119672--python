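"""Shared builders for synthetic sessions and traces."""

from __future__ import annotations

import numpy as np
import pytest

from pstnkit.photometry import DffTrace, PhotometrySession


@pytest.fixture
def make_session():
    """Build a PhotometrySession with sensible defaults."""

    def build(
        time_s,
        signal_465=None,
        signal_405=None,
        fs=None,
        subject="m01",
        trial="t000",
    ) -> PhotometrySession:
        t = np.asarray(time_s, dtype=float)
        if signal_465 is None:
            signal_465 = np.full(t.size, 100.0)
        if signal_405 is None:
            signal_405 = np.full(t.size, 80.0)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
        return PhotometrySession(
            subject_id=subject,
            trial_id=trial,
            time_s=t,
            signal_465=np.asarray(signal_465, dtype=float),
            signal_405=np.asarray(signal_405, dtype=float),
            sample_rate_hz=fs,
        )

    return build


@pytest.fixture
def make_trace():
    """Build a DffTrace directly from a dF/F vector."""

    def build(time_s, dff, subject="m01", trial="t000", excluded=False) -> DffTrace:
        return DffTrace(
            subject_id=subject,
            trial_id=trial,
            time_s=np.asarray(time_s, dtype=float),
            dff=np.asarray(dff, dtype=float),
            f_baseline=100.0,
            qc_excluded=excluded,
            qc_reason="screen" if excluded else "",
        )

    return build
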