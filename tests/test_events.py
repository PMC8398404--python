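"""Event detectors: gate segmentation, stabilization time, squat phases."""

import numpy as np
import pytest

from aclscreen.events import (
    JumpSegment,
    detect_contacts,
    detect_descending_phase,
    segment_squats,
    stabilization_time,
)
from aclscreen.signals import G, GateSignal, ImuTrial

FS = 1000.0


def _gate(flights, total=5.0):
    t = np.arange(int(total * FS)) / FS
    contact = np.ones(t.size, bool)
    for a, b in flights:
        contact[(t >= a) & (t < b)] = False
    return GateSignal(t=t, contact=contact, fs=FS)


def _trial_from_omega(omega, fs=FS):
    n = omega.size
    gyro = np.zeros((n, 3))
    gyro[:, 0] = omega
    acc = np.tile([0.0, 0.0, G], (n, 1))
    return ImuTrial(t=np.arange(n) / fs, accel=acc, gyro=gyro, fs=fs, task="mcmj")


class TestDetectContacts:
    def test_ideal_square_wave(self):
        segs = detect_contacts(_gate([(1.0, 1.4)]))
        assert len(segs) == 1
        s = segs[0]
        assert (s.FT_i, s.CT_i, s.dFT) == pytest.approx((1.0, 1.4, 0.4))

    def test_short_dropout_merged(self):
        gate = _gate([(1.0, 1.4), (2.0, 2.002)])  # 2 ms glitch inside contact
        segs = detect_contacts(gate)
        assert len(segs) == 1
        assert segs[0].CT_i == pytest.approx(1.4)

    def test_no_flight_warns_and_returns_empty(self):
        gate = _gate([])
        with pytest.warns(UserWarning, match="no complete flight"):
            assert detect_contacts(gate) == []

    def test_segmentation_invariant_to_prepended_stance(self):
        base = _gate([(1.0, 1.4)])
        longer = _gate([(3.0, 3.4)], total=7.0)
        s0, s1 = detect_contacts(base)[0], detect_contacts(longer)[0]
        assert s1.FT_i - s0.FT_i == pytest.approx(2.0)
        assert s1.dFT == pytest.approx(s0.dFT)


class TestStabilizationTime:
    @staticmethod
    def _damped_omega(trough_s, ct=1.0, dct=1.0, total=3.0, base=400.0, amp=400.0):
        t = np.arange(int(total * FS)) / FS
        omega = np.full(t.size, 30.0)
        tau = t - ct
        m = (tau >= 0) & (tau < dct)
        lam = 2.0
        w = np.pi / trough_s
        for _ in range(50):
            w = (np.pi - np.arctan2(lam, w)) / trough_s
        omega[m] = base + amp * np.exp(-lam * tau[m]) * np.cos(w * tau[m])
        return t, omega

    def test_trough_of_damped_oscillation(self):
        t, omega = self._damped_omega(0.20)
        trial = _trial_from_omega(omega)
        seg = JumpSegment(FT_i=0.6, CT_i=1.0, dFT=0.4, dCT=1.0)
        out = stabilization_time(trial, seg)
        assert out.Ts == pytest.approx(0.20, abs=0.005)
        assert not out.flagged

    def test_monotone_decrease_falls_back_to_window_end(self):
        t = np.arange(int(3 * FS)) / FS
        omega = np.maximum(500.0 - 200.0 * t, 10.0)
        trial = _trial_from_omega(omega)
        seg = JumpSegment(FT_i=0.6, CT_i=1.0, dFT=0.4, dCT=1.0)
        out = stabilization_time(trial, seg)
        assert out.Ts == pytest.approx(seg.dCT)
        assert out.flagged

    def test_shifting_trough_shifts_ts_equally(self):
        ts_list = []
        for trough in (0.18, 0.25):
            t, omega = self._damped_omega(trough)
            seg = JumpSegment(FT_i=0.6, CT_i=1.0, dFT=0.4, dCT=1.0)
            ts_list.append(stabilization_time(_trial_from_omega(omega), seg).Ts)
        assert ts_list[1] - ts_list[0] == pytest.approx(0.07, abs=0.005)


class TestDescendingPhase:
    @staticmethod
    def _angles(ramp_start=3.0, peak=28.0, ramp_dur=1.5, total=8.0, noise=0.0, seed=0):
        t = np.arange(int(total * FS)) / FS
        theta = np.zeros_like(t)
        m = (t >= ramp_start) & (t < ramp_start + 2 * ramp_dur)
        theta[m] = peak * np.sin(np.pi * (t[m] - ramp_start) / (2 * ramp_dur))
        rng = np.random.default_rng(seed)
        ang = np.zeros((t.size, 3))
        ang[:, 1] = theta
        if noise:
            ang += rng.normal(0, noise, ang.shape)
        return ang

    def test_noise_free_ramp_onset_and_peak(self):
        ang = self._angles()
        seg = detect_descending_phase(ang, FS)
        assert seg.DP_i == pytest.approx(3.0, abs=5 / FS)
        assert seg.DP_e == pytest.approx(4.5, abs=0.01)
        assert seg.theta_ymax == pytest.approx(28.0, abs=1e-6)

    def test_flat_series_flagged(self):
        ang = np.zeros((int(5 * FS), 3))
        with pytest.raises(ValueError, match="no squat detected"):
            detect_descending_phase(ang, FS)

    def test_segment_squats_one_segment_per_separated_rep(self):
        parts = []
        t = np.arange(int(12 * FS)) / FS
        theta = np.zeros_like(t)
        for start in (3.0, 7.0):  # separated by > 1 s quiet
            m = (t >= start) & (t < start + 3.0)
            theta[m] = 25.0 * np.sin(np.pi * (t[m] - start) / 3.0)
        rng = np.random.default_rng(1)
        ang = rng.normal(0, 0.05, (t.size, 3))
        ang[:, 1] += theta
        segs = segment_squats(ang, FS)
        assert len(segs) == 2
        assert segs[0].DP_i == pytest.approx(3.0, abs=0.02)
        assert segs[1].DP_i == pytest.approx(7.0, abs=0.02)
        assert [s.theta_ymax for s in segs] == pytest.approx([25.0, 25.0], abs=0.3)


def test_pipeline_event_recovery_against_ground_truth(mcmj_trial):
    _, trial, gate, truth = mcmj_trial
    segs = detect_contacts(gate)
    assert len(segs) == len(truth)
    for s, g in zip(segs, truth):
        assert s.CT_i == pytest.approx(g.CT_i, abs=1e-9)
        assert s.FT_i == pytest.approx(g.FT_i, abs=1e-9)
    for s, g in zip((stabilization_time(trial, s) for s in segs), truth):
        assert s.Ts == pytest.approx(g.Ts, abs=0.005)
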