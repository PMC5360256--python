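"""Transient detection, step measurement and event classification."""

import numpy as np
import pytest

import tetherforce as tf
from tetherforce.afm_calibration import ClampSegment
from tetherforce.event_detect import (
    DetectionParams,
    ForceTransient,
    detect_transients,
    measure_step,
)


def make_transient_trace(
    events,
    fs=1000.0,
    t0=100.0,
    duration=12.5,
    baseline=0.2,
    rise=0.004,
    noise_sd=0.0,
    seed=0,
):
    """events: list of (t_offset, amplitude_V, tau)."""
    t = t0 + np.arange(int(duration * fs)) / fs
    v = np.full_like(t, baseline)
    for off, amp, tau in events:
        s = t - (t0 + off)
        decay = np.exp(-np.maximum(s - rise, 0.0) / tau)
        v += amp * np.where(s < 0, 0.0, np.where(s < rise, s / rise, decay))
    if noise_sd > 0:
        v += np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    seg = ClampSegment(
        index=1, setpoint_v=baseline, t_span=(t0, t0 + duration), t_attain=t0
    )
    return t, v, seg


class TestDetectTransients:
    def test_noiseless_tau_within_two_percent(self):
        t, v, seg = make_transient_trace([(5.0, 0.1, 0.05)])
        trs = detect_transients(t, v, seg)
        assert len(trs) == 1
        tr = trs[0]
        assert tr.tau == pytest.approx(0.05, rel=0.02)
        assert tr.t_start < tr.t_vmax <= tr.t_end
        assert tr.t_start == pytest.approx(105.0, abs=0.01)

    def test_flat_trace_no_transients(self):
        t, v, seg = make_transient_trace([])
        assert detect_transients(t, v, seg) == []

    def test_two_well_separated_transients(self):
        tau = 0.05
        t, v, seg = make_transient_trace([(4.0, 0.1, tau), (4.0 + 10 * tau, 0.1, tau)])
        trs = detect_transients(t, v, seg)
        assert len(trs) == 2
        assert trs[0].t_vmax < trs[1].t_vmax

    def test_overlapping_peaks_merge_to_complex(self):
        tau = 0.1
        t, v, seg = make_transient_trace(
            [(5.0, 0.1, tau), (5.0 + tau, 0.1, tau)], noise_sd=0.005
        )
        trs = detect_transients(t, v, seg)
        near = [tr for tr in trs if 104.9 <= tr.t_vmax <= 105.4]
        assert len(near) == 1  # the two overlapping peaks form one event
        assert near[0].peak_count >= 2

    def test_short_segment_rejected(self):
        t, v, _ = make_transient_trace([])
        seg = ClampSegment(index=1, setpoint_v=0.2, t_span=(100.0, 101.0))
        with pytest.raises(ValueError):
            detect_transients(t, v, seg)

    def test_classification_is_total(self, default_run):
        *_, events, _ = default_run
        assert all(e.event_type in ("FC", "R", "F") for e in events)


class TestMeasureStep:
    def _step_trace(self, dz=7.0, slope=0.0, noise_sd=0.0, seed=0, fs=1000.0):
        t = np.arange(0.0, 4.0, 1.0 / fs)
        t_start, t_end = 2.0, 2.1
        z = slope * t + np.where(t >= (t_start + t_end) / 2, dz, 0.0)
        if noise_sd > 0:
            z = z + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
        tr = ForceTransient(
            t_start=t_start, t_end=t_end, t_vmax=2.01, v_max=0.1, t_half=2.005,
            rise_slope=10.0, tau=0.02,
        )
        return t, z, tr

    def test_ideal_step_machine_precision(self):
        t, z, tr = self._step_trace(dz=7.0)
        est = measure_step(t, z, tr)
        assert est.dz == pytest.approx(7.0, abs=1e-9)
        assert not est.truncated

    def test_no_step_reads_zero(self):
        t, z, tr = self._step_trace(dz=0.0)
        assert measure_step(t, z, tr).dz == pytest.approx(0.0, abs=1e-9)

    def test_step_on_creep_with_noise(self):
        """7 nm step on 2 nm/s creep, noise SD 0.5 nm: the two-line estimate
        stays within 0.5 nm."""
        t, z, tr = self._step_trace(dz=7.0, slope=2.0, noise_sd=0.5, seed=3)
        assert measure_step(t, z, tr).dz == pytest.approx(7.0, abs=0.5)

    def test_creep_exact_when_noiseless(self):
        t, z, tr = self._step_trace(dz=7.0, slope=2.0)
        assert measure_step(t, z, tr).dz == pytest.approx(7.0, abs=1e-9)

    def test_neighbor_truncates_window(self):
        t, z, tr = self._step_trace()
        nb = ForceTransient(
            t_start=2.25, t_end=2.3, t_vmax=2.26, v_max=0.1, t_half=2.255,
            rise_slope=10.0, tau=0.02,
        )
        est = measure_step(t, z, tr, neighbors=[nb])
        assert est.truncated
        assert est.dz == pytest.approx(7.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        t, z, tr = self._step_trace(fs=1000.0)
        with pytest.raises(ValueError):
            measure_step(t[::100], z[::100], tr)  # 10 Hz: 2 samples per window

    def test_dz_unbiased_over_many_events(self):
        """Mean dz error across paired events is within 2 SE of zero."""
        errs = []
        for i in range(20):
            cfg = tf.SimConfig(seed=300 + i, complex_prob=0.0, f_event_prob=0.0)
            rec, gt = tf.simulate_recording(cfg)
            _, events, _ = tf.analyze_recording(rec)
            for g in gt.events:
                if g.event_type != "FC":
                    continue
                m = [
                    e for e in events
                    if e.dz is not None and abs(e.transient.t_vmax - g.true_time) < 0.3
                ]
                if m:
                    errs.append(m[0].dz - g.true_dz)
        errs = np.asarray(errs)
        assert errs.size >= 150
        se = errs.std(ddof=1) / np.sqrt(errs.size)
        assert abs(errs.mean()) <= 2.0 * se + 1e-3


class TestClassification:
    def _segment(self):
        return ClampSegment(
            index=2, setpoint_v=0.2, t_span=(0.0, 12.5), t_attain=1.0,
            reached_setpoint=True,
        )

    def _transient(self, t_start, t_end):
        return ForceTransient(
            t_start=t_start, t_end=t_end, t_vmax=t_start + 0.01, v_max=0.1,
            t_half=t_start + 0.005, rise_slope=10.0, tau=0.02,
        )

    def test_fc_when_force_resumes(self):
        seg = self._segment()
        t = np.arange(0.0, 12.5, 0.001)
        v = np.full_like(t, 0.2)
        tr = self._transient(6.0, 6.2)
        assert tf.classify_event_type(tr, seg, t, v) == "FC"

    def test_r_before_setpoint_attained(self):
        seg = self._segment()
        t = np.arange(0.0, 12.5, 0.001)
        v = np.full_like(t, 0.2)
        tr = self._transient(0.5, 0.7)
        assert tf.classify_event_type(tr, seg, t, v) == "R"

    def test_f_when_deflection_stays_free(self):
        seg = self._segment()
        t = np.arange(0.0, 12.5, 0.001)
        v = np.where(t < 8.0, 0.2, 0.0)  # free level after the transient
        tr = self._transient(7.9, 8.0)
        assert tf.classify_event_type(tr, seg, t, v) == "F"

    @pytest.mark.parametrize(
        "shape, dz, expected",
        [
            ("unitary", 7.0, "S"),
            ("unitary", 501.0, "E"),
            ("complex", 7.0, "C_S"),
            ("complex", 501.0, "C_E"),
            ("unitary", 50.0, "E"),  # boundary assigned to extended
            ("complex", 50.0, "C_E"),
            ("unitary", None, None),
        ],
    )
    def test_shape_and_size_taxonomy(self, shape, dz, expected):
        assert tf.classify_shape_and_size(shape, dz) == expected


class TestClampDuration:
    def _segment(self, attain=0.5, reached=True):
        return ClampSegment(
            index=1, setpoint_v=0.2, t_span=(0.0, 12.5), t_attain=attain,
            reached_setpoint=reached,
        )

    def _event(self, etype, t_start, t_end):
        tr = ForceTransient(
            t_start=t_start, t_end=t_end, t_vmax=t_start, v_max=0.1,
            t_half=t_start, rise_slope=1.0, tau=0.01,
        )
        return tf.TetherEvent(
            transient=tr, dz=None, event_type=etype, shape="unitary",
            size_class=None, segment_index=1,
        )

    def test_full_segment_no_events(self):
        seg = self._segment(attain=0.0)
        assert tf.clamp_duration(seg, []) == pytest.approx(12.5)

    def test_f_event_truncates(self):
        seg = self._segment(attain=0.5)
        ev = self._event("F", 8.0, 8.1)
        assert tf.clamp_duration(seg, [ev]) == pytest.approx(7.5)

    def test_setpoint_never_reached_zero_flagged(self):
        seg = self._segment(reached=False)
        assert tf.clamp_duration(seg, []) == 0.0
        assert "no_clamp_duration" in seg.flags

    def test_schedule_total_sums_across_segments(self, quiet_config):
        """Four default segments, no F events: durations sum to the schedule
        total (ramp time excluded per segment)."""
        rec, _ = tf.simulate_recording(quiet_config)
        segments, _, _ = tf.analyze_recording(rec)
        total = sum(s.clamp_duration for s in segments)
        expect = 4 * (12.5 - quiet_config.ramp_duration)
        assert total == pytest.approx(expect, abs=0.2)
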