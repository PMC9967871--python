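"""SR Ca2+ store content and trans-sarcolemmal efflux from a caffeine bolus.

With stimulation and superfusion paused, a caffeine bolus empties the SR:
the transient's amplitude above the pre-caffeine diastolic level measures
the total SR Ca2+ store, and the decay time constant in the continued
presence of caffeine (SERCA re-uptake disabled) measures trans-sarcolemmal
Ca2+ efflux, dominated by NCX.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ValidationError
from .io import RatioTrace
from .transients import _fit_monoexp, _smooth


@dataclass(frozen=True)
class CaffeineConfig:
    pre_baseline_s: float = 2.0  # diastolic window before the bolus
    search_s: float = 10.0  # peak search window after the bolus
    min_post_s: float = 5.0  # minimum post-event record required
    smooth_width: int = 5
    noise_floor_k: float = 3.0  # response detection: amplitude > k * SD(baseline)
    onset_k: float = 5.0  # onset-detection fallback threshold
    return_frac: float = 0.05  # efflux fit ends on return to within 5% of amplitude


@dataclass
class CaffeineResult:
    store_amplitude: float
    tau_efflux: float
    fit_rmse: float
    fit_r2: float
    caffeine_time: float
    diastolic: float
    peak: float
    recovery_to_baseline: bool


def _detect_onset(signal: RatioTrace, cfg: CaffeineConfig) -> float:
    """Fallback for unannotated traces: first excursion above diastolic + k*SD."""
    t, y = signal.time, signal.signal
    base = y[t < t[0] + cfg.pre_baseline_s]
    if base.size < 10:
        raise AnalysisError("not enough pre-event samples to detect caffeine onset")
    mu, sd = float(np.mean(base)), float(np.std(base, ddof=1))
    above = np.flatnonzero(_smooth(y, cfg.smooth_width) > mu + cfg.onset_k * max(sd, 1e-12))
    if not above.size:
        raise AnalysisError("no caffeine response: no excursion above baseline noise")
    return float(t[above[0]])


def analyze_caffeine(
    signal: RatioTrace,
    caffeine_event: float | None = None,
    config: CaffeineConfig | None = None,
) -> CaffeineResult:
    """Quantify the caffeine transient of an unpaced recording.

    The event time comes from ``caffeine_event``, else from a ``caffeine``
    entry in the trace events, else from onset detection.
    """
    cfg = config or CaffeineConfig()
    t, y = signal.time, signal.signal
    if caffeine_event is None:
        marked = [ev_t for label, ev_t in signal.events if label.lower() == "caffeine"]
        caffeine_event = marked[0] if marked else _detect_onset(signal, cfg)
    t_ev = float(caffeine_event)
    if not (t[0] <= t_ev <= t[-1]):
        raise ValidationError("caffeine event time outside recording")
    if t[-1] - t_ev < cfg.min_post_s:
        raise AnalysisError(
            f"insufficient post-event record: {t[-1] - t_ev:.2f} s < {cfg.min_post_s} s"
        )

    base = y[(t >= t_ev - cfg.pre_baseline_s) & (t < t_ev)]
    if base.size < 10:
        raise AnalysisError("fewer than 10 pre-event baseline samples")
    diastolic = float(np.mean(base))
    base_sd = float(np.std(base, ddof=1))

    ys = _smooth(y, cfg.smooth_width)
    search = np.flatnonzero((t >= t_ev) & (t < t_ev + cfg.search_s))
    if float(np.max(ys[search])) - diastolic <= cfg.noise_floor_k * base_sd:
        raise AnalysisError("no caffeine response")
    # smoothed max screens the response; the raw argmax locates the peak and
    # the efflux fit below denoises its value (see transients.analyze_transient)
    ipeak = int(search[np.argmax(y[search])])
    peak = float(y[ipeak])
    amplitude = peak - diastolic
    if amplitude <= 0:
        raise AnalysisError("no caffeine response")

    # efflux fit: peak -> first return to within return_frac of amplitude, or record end
    post = np.arange(ipeak, t.size)
    returned = np.flatnonzero(ys[post] <= diastolic + cfg.return_frac * amplitude)
    i_end = int(post[returned[0]]) + 1 if returned.size else t.size
    if i_end - ipeak < 10:
        raise AnalysisError("decay segment too short for efflux fit")
    a_fit, tau, c_fit, rmse, r2 = _fit_monoexp(
        t[ipeak:i_end], y[ipeak:i_end], a0=amplitude, c0=diastolic,
        tau0=(t[i_end - 1] - t[ipeak]) / 3,
    )
    peak = a_fit + c_fit
    amplitude = peak - diastolic
    recovered = bool(abs(float(ys[-1]) - diastolic) <= cfg.return_frac * amplitude)
    return CaffeineResult(
        store_amplitude=amplitude,
        tau_efflux=tau,
        fit_rmse=rmse,
        fit_r2=r2,
        caffeine_time=t_ev,
        diastolic=diastolic,
        peak=peak,
        recovery_to_baseline=recovered,
    )
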