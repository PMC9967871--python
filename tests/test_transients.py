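"""Beat segmentation and kinetic-parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardioflux as cf
from cardioflux.errors import AnalysisError


def _ratio(t, y, **kw):
    return cf.RatioTrace(time=t, signal=y, kind="ratio", **kw)


class TestSegmentBeats:
    @pytest.mark.parametrize("freq,n_windows,width", [(1.0, 10, 1.0), (0.5, 5, 2.0)])
    def test_frequency_derived_windows(self, freq, n_windows, width):
        t = np.arange(4000) / 400.0  # 10 s
        windows = cf.segment_beats(_ratio(t, np.zeros(t.size)), stim_freq=freq)
        assert len(windows) == n_windows
        assert all(w.width == pytest.approx(width) for w in windows)
        assert windows[0].stim_time == 0.0

    def test_explicit_stim_times_override(self):
        t = np.arange(4000) / 400.0
        stims = [0.3, 1.3, 2.3, 3.3]
        windows = cf.segment_beats(_ratio(t, np.zeros(t.size)), stim_freq=1.0, stim_times=stims)
        assert [w.stim_time for w in windows] == stims

    def test_partial_final_window_dropped(self):
        t = np.arange(3900) / 400.0  # 9.75 s
        windows = cf.segment_beats(_ratio(t, np.zeros(t.size)), stim_freq=1.0)
        assert len(windows) == 9

    def test_too_short_recording(self):
        t = np.arange(400) / 400.0
        with pytest.raises(AnalysisError, match="two stimulus intervals"):
            cf.segment_beats(_ratio(t, np.zeros(t.size)), stim_freq=1.0)

    def test_no_stimulus_information(self, flat_ratio):
        with pytest.raises(AnalysisError, match="stim"):
            cf.segment_beats(flat_ratio)


class TestNoiselessRecovery:
    @pytest.mark.parametrize(
        "amp,tau,ttp,freq,mode",
        [
            (0.5, 0.27, 0.08, 0.5, "ratiometric"),
            (0.033, 0.30, 0.201, 0.1, "single"),
            (1.5, 0.15, 0.05, 0.5, "ratiometric"),
            (0.1, 1.00, 0.30, 0.1, "single"),
        ],
    )
    def test_kinetic_quintet(self, amp, tau, ttp, freq, mode):
        dia = 1.0 if mode == "ratiometric" else 0.0
        spec = cf.TransientGenSpec(
            seed=5, diastolic=dia, amplitude=amp, time_to_peak_s=ttp, tau_decay_s=tau,
            stim_freq_hz=freq, n_beats=4, noise_sd=0.0, mode=mode, pre_quiet_s=2.0,
        )
        trace, truth = cf.gen_transient_trace(spec)
        if mode == "ratiometric":
            sig = cf.compute_ratio(trace)
        else:
            sig = cf.compute_dff(trace, truth["f0_window"])
        s = cf.steady_state_summary(cf.analyze_trace(sig), n_last=3)
        dt = 1.0 / spec.sampling_rate_hz
        assert s.mean["amplitude"] == pytest.approx(amp, rel=5e-3)
        assert s.mean["tau_decay"] == pytest.approx(tau, rel=5e-3)
        assert s.mean["diastolic"] == pytest.approx(dia, abs=2e-3 * max(amp, 1e-6) + 1e-9)
        assert s.mean["time_to_peak"] == pytest.approx(ttp, abs=dt + 1e-9)
        # onset discretisation + smoothing understate the derivative maximum
        assert 0.6 * truth["max_rate_of_rise"] < s.mean["max_rate_of_rise"] <= 1.02 * truth["max_rate_of_rise"]

    def test_tau_matches_loglinear_oracle(self):
        # instantaneous-release beat: the decay limb is a pure exponential
        t = np.arange(0, 6, 1 / 400)
        dia, amp, tau = 1.2, 0.8, 0.45
        y = np.full(t.size, dia)
        decay = t >= 2.0
        y[decay] = dia + amp * np.exp(-(t[decay] - 2.0) / tau)
        sig = _ratio(t, y)
        params = cf.analyze_transient(
            sig, cf.BeatWindow(index=0, stim_time=2.0, t_start=2.0, t_end=6.0)
        )
        sel = decay & (y > dia + 1e-6)
        slope = np.polyfit(t[sel], np.log(y[sel] - dia), 1)[0]
        assert params.tau_decay == pytest.approx(-1.0 / slope, rel=1e-8)
        assert params.fit_r2 > 1 - 1e-12


class TestRejectionAndSummary:
    def test_flat_beat_rejected(self, flat_ratio):
        params = cf.analyze_transient(
            flat_ratio, cf.BeatWindow(index=0, stim_time=1.0, t_start=1.0, t_end=2.0)
        )
        assert not params.accepted
        assert "noise floor" in params.reason

    def test_summary_requires_enough_accepted(self, paced_ratio):
        _, _, sig = paced_ratio
        params = cf.analyze_trace(sig)
        with pytest.raises(AnalysisError, match="accepted beats"):
            cf.steady_state_summary(params, n_last=len(params) + 1)

    def test_sem_matches_bruteforce(self, paced_ratio):
        _, _, sig = paced_ratio
        params = cf.analyze_trace(sig)
        s = cf.steady_state_summary(params, n_last=4)
        amps = np.array([p.amplitude for p in params if p.accepted][-4:])
        assert s.mean["amplitude"] == pytest.approx(amps.mean(), rel=1e-12)
        assert s.sem["amplitude"] == pytest.approx(amps.std(ddof=1) / 2.0, rel=1e-9)

    def test_identical_beats_have_zero_sem(self):
        # steady-state beats of a noiseless train are identical
        spec = cf.TransientGenSpec(seed=3, noise_sd=0.0, stim_freq_hz=0.5, n_beats=8)
        trace, _ = cf.gen_transient_trace(spec)
        s = cf.steady_state_summary(cf.analyze_trace(cf.compute_ratio(trace)), n_last=4)
        assert s.sem["amplitude"] == pytest.approx(0.0, abs=1e-7)
        assert s.sem["tau_decay"] == pytest.approx(0.0, abs=1e-7)


class TestInvariances:
    def test_time_shift_equivariance(self, paced_ratio):
        _, _, sig = paced_ratio
        delta = 3.7
        shifted = cf.RatioTrace(
            time=sig.time + delta, signal=sig.signal.copy(), kind="ratio",
            stim_freq=sig.stim_freq, stim_times=sig.stim_times + delta,
        )
        p0 = cf.analyze_trace(sig)
        p1 = cf.analyze_trace(shifted)
        for a, b in zip(p0, p1):
            assert b.amplitude == pytest.approx(a.amplitude, rel=1e-9)
            assert b.time_to_peak == pytest.approx(a.time_to_peak, abs=1e-9)
            assert b.tau_decay == pytest.approx(a.tau_decay, rel=1e-7)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(offset=st.floats(min_value=-5, max_value=5))
    def test_offset_shifts_diastolic_not_amplitude(self, offset):
        spec = cf.TransientGenSpec(seed=7, noise_sd=0.0, stim_freq_hz=0.5, n_beats=3)
        trace, _ = cf.gen_transient_trace(spec)
        sig = cf.compute_ratio(trace)
        moved = cf.RatioTrace(
            time=sig.time, signal=sig.signal + offset, kind="ratio",
            stim_freq=sig.stim_freq, stim_times=sig.stim_times,
        )
        p0 = cf.analyze_trace(sig)[-1]
        p1 = cf.analyze_trace(moved)[-1]
        assert p1.amplitude == pytest.approx(p0.amplitude, rel=1e-6)
        assert p1.diastolic - p0.diastolic == pytest.approx(offset, abs=1e-9)


class TestNoisyRecovery:
    def test_median_error_under_two_percent_noise(self):
        """Gaussian noise at 2% of amplitude: median tau/amp error < 5%."""
        errs_tau, errs_amp = [], []
        for seed in range(20):
            spec = cf.TransientGenSpec(seed=seed, noise_sd=0.01, n_beats=20)
            trace, truth = cf.gen_transient_trace(spec)
            s = cf.steady_state_summary(cf.analyze_trace(cf.compute_ratio(trace)), n_last=10)
            errs_tau.append(abs(s.mean["tau_decay"] / truth["tau_decay"] - 1))
            errs_amp.append(abs(s.mean["amplitude"] / truth["amplitude"] - 1))
        assert np.median(errs_tau) < 0.05
        assert np.median(errs_amp) < 0.05

    def test_mitochondrial_slower_than_cytosolic(self):
        """Paired traces from the two parameter sets: mito TTP > cyto TTP."""
        cyto = cf.TransientGenSpec(seed=1, amplitude=1.41, time_to_peak_s=0.08,
                                   tau_decay_s=0.27, noise_sd=0.02, n_beats=6)
        mito = cf.TransientGenSpec(seed=1, diastolic=0.0, amplitude=0.025,
                                   time_to_peak_s=0.165, tau_decay_s=0.30,
                                   stim_freq_hz=0.5, noise_sd=0.0025, n_beats=6,
                                   mode="single", pre_quiet_s=2.0)
        tr_c, _ = cf.gen_transient_trace(cyto)
        tr_m, tm = cf.gen_transient_trace(mito)
        s_c = cf.steady_state_summary(cf.analyze_trace(cf.compute_ratio(tr_c)), n_last=4)
        s_m = cf.steady_state_summary(
            cf.analyze_trace(cf.compute_dff(tr_m, tm["f0_window"])), n_last=4
        )
        assert s_m.mean["time_to_peak"] > s_c.mean["time_to_peak"]
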