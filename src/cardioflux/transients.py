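"""Beat segmentation and per-transient kinetic parameters.

A paced recording is cut into one window per stimulus and each beat is
reduced to the kinetic quintet used throughout the cardiac Ca2+ literature:
diastolic level, amplitude (peak - diastolic), maximum rate of rise,
time to peak, and the monoexponential decay time constant tau fitted as

    y(t) = A * exp(-(t - t_p) / tau) + C

with the offset C free, so residual baseline drift does not bias tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import AnalysisError, ValidationError
from .io import RatioTrace
from .waveform import solve_rise_tau, transient_kernel

_PARAM_FIELDS = (
    "diastolic",
    "peak",
    "amplitude",
    "max_rate_of_rise",
    "time_to_peak",
    "tau_decay",
    "fit_rmse",
    "fit_r2",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the per-beat analysis (defaults are package-pinned).

    baseline_ms
        Length of the diastolic baseline segment in ms.
    baseline_mode
        "pre": the segment immediately *preceding* the stimulus (falls back
        to "post" for a first beat without pre-stimulus samples);
        "post": the first ``baseline_ms`` of the beat window.
    smooth_width
        Moving-average width in samples applied before peak/derivative
        detection (12.5 ms at 400 Hz for the default 5).
    decay_fit_start
        "peak" starts the tau fit at the peak sample; "frac" starts where
        the smoothed signal has fallen to ``decay_fit_frac`` of amplitude.
    decay_fit_delay_s
        Extra delay added to the fit start (the spec's ``d``), default 0.
    noise_floor_k
        Beats with amplitude <= k * SD(baseline) are rejected.
    ttp_reference
        "stimulus" measures time-to-peak from the stimulus; "onset" from the
        first sample exceeding diastolic + k * SD(baseline).
    waveform_fit
        Refine amplitude and time-to-peak by a full rise-and-decay template
        fit of the beat: "auto" (default) does so only when the beat SNR
        (amplitude / baseline SD) falls below ``waveform_fit_snr``, where
        single-sample peak estimators carry extreme-value bias; "always" /
        "never" force the choice.  The decay tau always comes from the
        monoexponential tail fit.
    """

    baseline_ms: float = 50.0
    baseline_mode: str = "pre"
    smooth_width: int = 5
    decay_fit_start: str = "peak"
    decay_fit_frac: float = 0.9
    decay_fit_delay_s: float = 0.0
    noise_floor_k: float = 3.0
    ttp_reference: str = "stimulus"
    waveform_fit: str = "auto"
    waveform_fit_snr: float = 20.0

    def __post_init__(self) -> None:
        if self.baseline_mode not in ("pre", "post"):
            raise ValidationError("baseline_mode must be 'pre' or 'post'")
        if self.decay_fit_start not in ("peak", "frac"):
            raise ValidationError("decay_fit_start must be 'peak' or 'frac'")
        if self.ttp_reference not in ("stimulus", "onset"):
            raise ValidationError("ttp_reference must be 'stimulus' or 'onset'")
        if self.waveform_fit not in ("auto", "always", "never"):
            raise ValidationError("waveform_fit must be 'auto', 'always' or 'never'")
        if self.smooth_width < 1 or self.smooth_width % 2 == 0:
            raise ValidationError("smooth_width must be a positive odd integer")


@dataclass(frozen=True)
class BeatWindow:
    """One stimulus interval ``[t_start, t_end)`` of a paced recording."""

    index: int
    stim_time: float
    t_start: float
    t_end: float

    @property
    def width(self) -> float:
        return self.t_end - self.t_start


@dataclass
class TransientParams:
    """Kinetic parameters of a single Ca2+ transient.

    ``max_rate_of_rise`` is in signal units per ms; times in seconds.
    ``accepted`` is False for beats rejected at the noise floor and
    ``tau_valid`` is False when the decay fit did not converge.
    """

    beat_index: int
    diastolic: float = math.nan
    peak: float = math.nan
    amplitude: float = math.nan
    max_rate_of_rise: float = math.nan
    time_to_peak: float = math.nan
    tau_decay: float = math.nan
    fit_rmse: float = math.nan
    fit_r2: float = math.nan
    accepted: bool = True
    tau_valid: bool = True
    reason: str = ""


@dataclass
class SteadyStateSummary:
    """Mean +/- SEM of each parameter over the last n accepted beats."""

    mean: dict[str, float]
    sem: dict[str, float]
    n_beats: int
    rejected: list[tuple[int, str]] = field(default_factory=list)


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y.copy()
    pad = width // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, np.ones(width) / width, mode="valid")


def segment_beats(
    signal: RatioTrace,
    stim_freq: float | None = None,
    stim_times: Sequence[float] | None = None,
) -> list[BeatWindow]:
    """One window per stimulus, ``[stim, stim + period)``.

    Explicit ``stim_times`` (argument or carried on the trace) override the
    frequency-derived train, which starts at the first sample.  A final
    window not fully covered by the recording is dropped.
    """
    if stim_times is None and signal.stim_times is not None and len(signal.stim_times):
        stim_times = signal.stim_times
    freq = stim_freq if stim_freq is not None else signal.stim_freq
    dt = 1.0 / signal.sampling_rate
    t0, t_end = float(signal.time[0]), float(signal.time[-1])

    if stim_times is not None and len(stim_times):
        stims = np.sort(np.asarray(stim_times, dtype=float))
        if freq and freq > 0:
            period = 1.0 / freq
        elif stims.size >= 2:
            period = float(np.median(np.diff(stims)))
        else:
            raise AnalysisError("a single explicit stimulus needs stim_freq for the window width")
    else:
        if not freq or freq <= 0:
            raise AnalysisError("need stim_freq > 0 or explicit stim_times")
        period = 1.0 / freq
        stims = np.arange(t0, t_end + dt / 2, period)

    if t_end - t0 < 2 * period - dt:
        raise AnalysisError("recording shorter than two stimulus intervals")

    windows = []
    for i, s in enumerate(stims):
        end = s + period
        if s < t0 - dt / 2:
            continue
        if end > t_end + dt:  # partial final window
            continue
        windows.append(BeatWindow(index=len(windows), stim_time=float(s), t_start=float(s), t_end=float(end)))
    if not windows:
        raise AnalysisError("zero usable beat windows in recording")
    return windows


def _fit_monoexp(t: np.ndarray, y: np.ndarray, a0: float, c0: float, tau0: float):
    """Least-squares A*exp(-(t-t0)/tau)+C; returns (A, tau, C, rmse, r2)."""
    t0 = t[0]

    def model(tt, a, tau, c):
        return a * np.exp(-(tt - t0) / tau) + c

    # log-linear seed for tau where the signal is cleanly above the offset
    resid = y - c0
    pos = resid > max(1e-12, 0.05 * abs(a0))
    if pos.sum() >= 3:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        if slope < 0:
            tau0 = -1.0 / slope
    p, _ = curve_fit(
        model,
        t,
        y,
        p0=[a0, max(tau0, 1e-6), c0],
        bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    yhat = model(t, *p)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    rmse = math.sqrt(ss_res / t.size)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(p[0]), float(p[1]), float(p[2]), rmse, r2


def _fit_waveform(tw: np.ndarray, yw: np.ndarray, amp0: float, ttp0: float, tau0: float, base0: float):
    """Least-squares rise-and-decay template fit; returns (amp, ttp, tau_d)."""

    def model(t, amp, ttp, tau_d, base):
        tau_r = solve_rise_tau(min(ttp, 0.95 * tau_d), tau_d)
        return base + amp * transient_kernel(t, tau_r, tau_d)

    width = float(tw[-1] - tw[0])
    p, _ = curve_fit(
        model,
        tw,
        yw,
        p0=[amp0, min(max(ttp0, 1e-3), 0.5 * width), max(tau0, 1e-3), base0],
        bounds=([1e-9, 1e-4, 1e-3, -np.inf], [np.inf, width, 100.0 * width, np.inf]),
        maxfev=10000,
    )
    return float(p[0]), float(p[1]), float(p[2])


def analyze_transient(
    signal: RatioTrace,
    window: BeatWindow,
    config: AnalysisConfig | None = None,
) -> TransientParams:
    """Extract the kinetic quintet from one beat window."""
    cfg = config or AnalysisConfig()
    t, y = signal.time, signal.signal
    dt = 1.0 / signal.sampling_rate
    sel = (t >= window.t_start - dt / 2) & (t < window.t_end - dt / 2)
    idx = np.flatnonzero(sel)
    if idx.size < 20:
        raise AnalysisError(f"beat window {window.index} has {idx.size} samples; need >= 20")
    tw, yw = t[idx], y[idx]

    # --- diastolic baseline
    b = cfg.baseline_ms / 1000.0
    base = np.empty(0)
    if cfg.baseline_mode == "pre":
        pre = (t >= window.stim_time - b - dt / 2) & (t < window.stim_time - dt / 2)
        base = y[pre]
    if base.size < 2:  # first beat or 'post' mode
        base = yw[tw < window.t_start + b]
    if base.size < 2:
        raise AnalysisError(f"baseline segment of beat {window.index} has < 2 samples")
    diastolic = float(np.mean(base))
    base_sd = float(np.std(base, ddof=1))

    # --- peak: smoothed max screens against noise, raw argmax locates it.
    # The raw argmax is exact on noiseless data and free of the early shift
    # a moving average imposes on an asymmetric peak; the peak *value* is
    # then denoised through the decay fit below.
    ys = _smooth(yw, cfg.smooth_width)
    peak_s = float(np.max(ys))
    if peak_s - diastolic <= cfg.noise_floor_k * base_sd or peak_s <= diastolic:
        return TransientParams(
            beat_index=window.index, diastolic=diastolic, peak=peak_s,
            amplitude=peak_s - diastolic, accepted=False, tau_valid=False,
            reason="amplitude below noise floor",
        )
    ipeak = int(np.argmax(yw))
    peak = float(yw[ipeak])
    amplitude = peak - diastolic
    out = TransientParams(beat_index=window.index, diastolic=diastolic, peak=peak, amplitude=amplitude)
    noise_floor = cfg.noise_floor_k * base_sd

    # --- time to peak
    if cfg.ttp_reference == "onset":
        above = np.flatnonzero(ys > diastolic + noise_floor)
        ref = float(tw[above[0]]) if above.size else window.stim_time
    else:
        ref = window.stim_time
    out.time_to_peak = float(tw[ipeak] - ref)

    # --- max rate of rise between stimulus and peak, per ms
    if ipeak >= 2:
        deriv = np.gradient(ys, tw)
        out.max_rate_of_rise = float(np.max(deriv[: ipeak + 1])) / 1000.0
    else:
        out.max_rate_of_rise = amplitude / max(out.time_to_peak, dt) / 1000.0

    # --- decay fit
    i0 = ipeak
    if cfg.decay_fit_start == "frac":
        thresh = diastolic + cfg.decay_fit_frac * amplitude
        below = np.flatnonzero(ys[ipeak:] <= thresh)
        if below.size:
            i0 = ipeak + int(below[0])
    if cfg.decay_fit_delay_s > 0:
        i0 += int(round(cfg.decay_fit_delay_s / dt))
    if idx.size - i0 < 5:
        out.tau_valid = False
        out.reason = "too few samples after peak for decay fit"
        return out
    try:
        a_fit, tau, c_fit, rmse, r2 = _fit_monoexp(
            tw[i0:], yw[i0:], a0=amplitude, c0=diastolic, tau0=(tw[-1] - tw[i0]) / 3
        )
        out.tau_decay, out.fit_rmse, out.fit_r2 = tau, rmse, r2
        if cfg.decay_fit_start == "peak" and cfg.decay_fit_delay_s == 0:
            # denoised peak: the fitted decay evaluated at its anchor, which
            # averages the whole decay limb instead of a single noisy sample
            out.peak = a_fit + c_fit
            out.amplitude = out.peak - diastolic
    except (RuntimeError, ValueError) as exc:
        out.tau_valid = False
        out.reason = f"decay fit did not converge: {exc}"

    snr = out.amplitude / base_sd if base_sd > 0 else math.inf
    if cfg.waveform_fit == "always" or (cfg.waveform_fit == "auto" and snr < cfg.waveform_fit_snr):
        try:
            tau0 = out.tau_decay if out.tau_valid and math.isfinite(out.tau_decay) else (tw[-1] - tw[0]) / 3
            amp_w, ttp_w, _ = _fit_waveform(
                tw - window.stim_time, yw,
                amp0=out.amplitude, ttp0=out.time_to_peak, tau0=tau0, base0=diastolic,
            )
            out.amplitude = amp_w
            out.peak = diastolic + amp_w
            if cfg.ttp_reference == "stimulus":
                out.time_to_peak = ttp_w
        except (RuntimeError, ValueError, ValidationError):
            pass  # template did not converge: keep the sample-based estimates
    return out


def analyze_trace(
    signal: RatioTrace,
    stim_freq: float | None = None,
    stim_times: Sequence[float] | None = None,
    config: AnalysisConfig | None = None,
) -> list[TransientParams]:
    """Segment a paced trace and analyze every beat."""
    windows = segment_beats(signal, stim_freq=stim_freq, stim_times=stim_times)
    return [analyze_transient(signal, w, config) for w in windows]


def steady_state_summary(params: Sequence[TransientParams], n_last: int) -> SteadyStateSummary:
    """Mean +/- SEM of each parameter over the last ``n_last`` accepted beats."""
    if n_last < 1:
        raise ValidationError("n_last must be >= 1")
    accepted = [p for p in params if p.accepted and p.tau_valid]
    rejected = [(p.beat_index, p.reason) for p in params if not (p.accepted and p.tau_valid)]
    if len(accepted) < n_last:
        raise AnalysisError(
            f"only {len(accepted)} accepted beats of {len(params)}; need n_last={n_last}"
        )
    tail = accepted[-n_last:]
    mean, sem = {}, {}
    for f in _PARAM_FIELDS:
        vals = np.array([getattr(p, f) for p in tail], dtype=float)
        mean[f] = float(np.mean(vals))
        sem[f] = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return SteadyStateSummary(mean=mean, sem=sem, n_beats=len(tail), rejected=rejected)
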