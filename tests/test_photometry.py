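"""Unit and property tests for the photometry pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pstnkit.photometry import (
    auc_to_zero,
    compute_dff,
    downsample_1hz,
    max_dff,
    qc_artifact_flag,
    summarize_group,
)


def baseline_times(post_n=120, fs=1.0):
    return np.arange(-30 * fs, post_n * fs) / fs


class TestDownsample:
    def test_bin_means_and_labels(self, make_session):
        # 4 Hz over [0, 2): bins [0,1) -> mean 2.5, [1,2) -> mean 6.5
        t = np.arange(8) / 4.0
        s = make_session(t, signal_465=[1, 2, 3, 4, 5, 6, 7, 8], fs=4.0)
        out = downsample_1hz(s)
        assert out.time_s.tolist() == [0.0, 1.0]
        assert out.signal_465.tolist() == [2.5, 6.5]
        assert out.sample_rate_hz == 1.0

    def test_constant_channel_stays_constant(self, make_session):
        t = np.arange(-600, 600) / 20.0
        out = downsample_1hz(make_session(t, signal_465=np.full(t.size, 7.0), fs=20.0))
        assert np.allclose(out.signal_465, 7.0)

    def test_bin_edge_at_event_time(self, make_session):
        # samples at +/-0.25 s land in bins -1 and 0: no bin straddles t=0
        t = np.array([-1.75, -1.25, -0.75, -0.25, 0.25, 0.75, 1.25, 1.75])
        out = downsample_1hz(make_session(t, signal_465=[0, 0, 1, 1, 2, 2, 3, 3], fs=2.0))
        assert out.time_s.tolist() == [-2.0, -1.0, 0.0, 1.0]
        assert out.signal_465.tolist() == [0.0, 1.0, 2.0, 3.0]

    def test_channels_downsampled_independently(self, make_session):
        rng = np.random.default_rng(0)
        t = np.arange(-100, 100) / 10.0
        a = rng.normal(100, 5, t.size)
        b = rng.normal(80, 5, t.size)
        both = downsample_1hz(make_session(t, signal_465=a, signal_405=b, fs=10.0))
        only_a = downsample_1hz(make_session(t, signal_465=a, fs=10.0))
        only_b = downsample_1hz(make_session(t, signal_405=b, fs=10.0))
        assert np.array_equal(both.signal_465, only_a.signal_465)
        assert np.array_equal(both.signal_405, only_b.signal_405)

    def test_cannot_upsample(self, make_session):
        t = np.arange(0, 20, 2.0)
        with pytest.raises(ValueError, match="cannot downsample upward"):
            downsample_1hz(make_session(t, fs=0.5))

    def test_non_monotone_time_rejected(self, make_session):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_session([0.0, 1.0, 0.5, 2.0], fs=1.0)


class TestComputeDff:
    def test_formula_against_hand_value(self, make_session):
        t = baseline_times()
        f = np.where(t < 0, 10.0, 12.0)
        trace = compute_dff(make_session(t, signal_465=f))
        assert trace.f_baseline == 10.0
        assert np.allclose(trace.dff[t >= 0], 0.2)

    def test_constant_signal_gives_zero(self, make_session):
        t = baseline_times()
        trace = compute_dff(make_session(t, signal_465=np.full(t.size, 10.0)))
        assert np.allclose(trace.dff, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=1000.0))
    def test_scale_invariance(self, scale):
        t = baseline_times()
        rng = np.random.default_rng(1)
        f = rng.uniform(50, 150, t.size)
        base = compute_dff(
            _quick_session(t, f)
        )
        scaled = compute_dff(_quick_session(t, scale * f))
        assert np.allclose(base.dff, scaled.dff, atol=1e-9)

    def test_baseline_median_of_dff_is_zero(self, make_session):
        t = baseline_times()
        rng = np.random.default_rng(2)
        f = rng.uniform(90, 110, t.size)
        trace = compute_dff(make_session(t, signal_465=f))
        assert abs(np.median(trace.dff[(t >= -30) & (t < 0)])) < 1e-12

    def test_nonpositive_baseline_rejected(self, make_session):
        t = baseline_times()
        f = np.where(t < 0, -5.0, 10.0)
        with pytest.raises(ValueError, match="non-positive baseline"):
            compute_dff(make_session(t, signal_465=f))

    def test_short_baseline_rejected(self, make_session):
        t = np.arange(-10, 60, 1.0)
        with pytest.raises(ValueError, match="insufficient baseline"):
            compute_dff(make_session(t))


def _quick_session(t, f465, f405=None):
    from pstnkit.photometry import PhotometrySession

    return PhotometrySession(
        "m", "t", t, f465, f405 if f405 is not None else np.full(t.size, 80.0), 1.0
    )


class TestQcFlag:
    def test_flat_control_retained(self, make_session):
        t = baseline_times()
        excluded, reason = qc_artifact_flag(make_session(t))
        assert not excluded and reason == ""

    @pytest.mark.parametrize(
        "peak, expect",
        [(125.0, True), (119.0, False), (75.0, True), (81.0, False)],
    )
    def test_boundary_semantics_strict(self, make_session, peak, expect):
        # baseline median 100; 25% beyond threshold excluded, 19% retained
        t = baseline_times()
        c = np.full(t.size, 100.0)
        c[t == 40.0] = peak
        excluded, reason = qc_artifact_flag(make_session(t, signal_405=c))
        assert excluded is expect
        if expect:
            assert "t=40" in reason and "20%" in reason

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        lo=st.floats(min_value=0.0, max_value=0.5),
        hi=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_raising_threshold_never_excludes_more(self, lo, hi):
        lo, hi = sorted((lo, hi))
        t = baseline_times()
        rng = np.random.default_rng(3)
        c = rng.uniform(80, 120, t.size)
        s = _quick_session(t, np.full(t.size, 100.0), c)
        if not qc_artifact_flag(s, threshold=lo)[0]:
            assert not qc_artifact_flag(s, threshold=hi)[0]


class TestMetrics:
    def test_max_dff_respects_window(self, make_trace):
        t = np.arange(0, 120, 1.0)
        dff = np.full(t.size, 0.1)
        dff[t == 80] = 0.5
        assert max_dff(make_trace(t, dff)) == pytest.approx(0.1)

    def test_max_dff_finds_peak(self, make_trace):
        t = np.arange(0, 120, 1.0)
        dff = np.zeros(t.size)
        dff[t == 30] = 0.4
        assert max_dff(make_trace(t, dff)) == pytest.approx(0.4)
        assert max_dff(make_trace(t, np.zeros(t.size))) == 0.0

    def test_max_dff_refuses_excluded_trace(self, make_trace):
        t = np.arange(0, 120, 1.0)
        with pytest.raises(ValueError, match="QC-excluded"):
            max_dff(make_trace(t, np.zeros(t.size), excluded=True))

    def test_max_dff_empty_window(self, make_trace):
        t = np.arange(0, 10, 1.0)
        with pytest.raises(ValueError, match="window"):
            max_dff(make_trace(t, np.zeros(t.size)), window_s=(50.0, 75.0))

    def test_upward_shift_never_decreases_max(self, make_trace):
        t = np.arange(0, 76, 1.0)
        rng = np.random.default_rng(4)
        dff = rng.normal(0, 0.1, t.size)
        base = max_dff(make_trace(t, dff))
        assert max_dff(make_trace(t, dff + 0.05)) >= base

    def test_auc_hand_trapezoid(self, make_trace):
        auc, t_ret = auc_to_zero(make_trace([0, 1, 2, 3], [1.0, 1.0, 1.0, 0.0]))
        assert auc == pytest.approx(2.5)
        assert t_ret == 3.0

    def test_auc_zero_trace(self, make_trace):
        auc, t_ret = auc_to_zero(make_trace(np.arange(5.0), np.zeros(5)))
        assert auc == 0.0
        assert t_ret == 1.0

    def test_auc_never_returns(self, make_trace):
        t = np.arange(0, 10, 1.0)
        auc, t_ret = auc_to_zero(make_trace(t, np.full(t.size, 1.0)))
        assert t_ret is None
        assert auc == pytest.approx(9.0)

    def test_auc_negative_onset_symmetric(self, make_trace):
        auc, t_ret = auc_to_zero(make_trace([0, 1, 2, 3], [-1.0, -1.0, -1.0, 0.0]))
        assert auc == pytest.approx(-2.5)
        assert t_ret == 3.0

    def test_auc_converges_to_closed_form_with_density(self, make_trace):
        # dF/F = A exp(-t/tau): integral A*tau; dense trapezoid approaches it
        amplitude, tau = 0.4, 10.0
        t = np.arange(0, 200, 0.01)
        auc, t_ret = auc_to_zero(make_trace(t, amplitude * np.exp(-t / tau)))
        assert t_ret is None
        assert auc == pytest.approx(amplitude * tau, rel=1e-3)

    def test_auc_sign_matches_trace_sign(self, make_trace):
        t = np.arange(0, 50, 1.0)
        dff = np.maximum(0.3 - 0.01 * t, 0.0)
        auc, _ = auc_to_zero(make_trace(t, dff))
        assert auc >= 0.0


class TestGroupSummary:
    def test_mean_and_sem_hand_values(self, make_trace):
        t = np.arange(0, 10, 1.0)
        traces = [
            make_trace(t, np.full(t.size, v), subject=f"m{v}") for v in (1.0, 2.0, 3.0)
        ]
        g = summarize_group(traces)
        assert np.allclose(g.mean_dff, 2.0)
        assert np.allclose(g.sem_dff, 1.0 / math.sqrt(3))
        assert g.heatmap.shape == (3, t.size)

    def test_symmetric_traces_cancel(self, make_trace):
        t = np.arange(0, 10, 1.0)
        x = np.sin(t)
        g = summarize_group(
            [make_trace(t, x, subject="a"), make_trace(t, -x, subject="b")]
        )
        assert np.allclose(g.mean_dff, 0.0)

    def test_single_trace_sem_zero_and_flagged(self, make_trace):
        t = np.arange(0, 10, 1.0)
        g = summarize_group([make_trace(t, np.ones(t.size))])
        assert np.allclose(g.sem_dff, 0.0)
        assert g.sem_undefined

    def test_excluded_traces_dropped_and_counted(self, make_trace):
        t = np.arange(0, 10, 1.0)
        g = summarize_group(
            [
                make_trace(t, np.ones(t.size), subject="a"),
                make_trace(t, np.full(t.size, 9.0), subject="b", excluded=True),
            ]
        )
        assert g.heatmap.shape[0] == 1
        assert g.n_excluded == 1
        assert np.allclose(g.mean_dff, 1.0)

    def test_all_excluded_is_an_error(self, make_trace):
        t = np.arange(0, 10, 1.0)
        with pytest.raises(ValueError, match="no analyzable trials"):
            summarize_group([make_trace(t, np.ones(t.size), excluded=True)])

    def test_rows_ordered_by_subject(self, make_trace):
        t = np.arange(0, 5, 1.0)
        g = summarize_group(
            [
                make_trace(t, np.full(t.size, 2.0), subject="m02"),
                make_trace(t, np.full(t.size, 1.0), subject="m01"),
            ]
        )
        assert g.subject_ids == ["m01", "m02"]
        assert g.heatmap[0, 0] == 1.0
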