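"""The Ca2+-transient waveform template shared by generator and fitters.

The template rises as a product of exponentials and decays exactly
monoexponentially, with unit peak at ``t* = tau_r ln(1 + tau_d/tau_r)``::

    g(t) = (1 - exp(-t/tau_r)) exp(-t/tau_d) / g(t*)   for 0 <= t <= t*
    g(t) = exp(-(t - t*) / tau_d)                      for t > t*

Amplitude, time-to-peak and decay tau are therefore independent, analytic
parameters: the rise constant is recovered from a requested time-to-peak
through the closed peak-time relation, and the decay limb carries a single
well-defined tau however close to the peak a fit starts.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError


def solve_rise_tau(time_to_peak: float, tau_decay: float) -> float:
    """Rise constant tau_r whose peak time ``tau_r ln(1 + tau_d/tau_r)``
    equals ``time_to_peak``.

    The peak time increases monotonically in tau_r and approaches tau_d
    from below, so a solution exists iff ``time_to_peak < tau_decay``.
    """
    if time_to_peak <= 0 or tau_decay <= 0:
        raise ValidationError("time constants must be positive")
    if time_to_peak >= tau_decay:
        raise ValidationError(
            f"unreachable time-to-peak {time_to_peak} s: must be < tau_decay {tau_decay} s"
        )

    def f(tr: float) -> float:
        return tr * math.log1p(tau_decay / tr) - time_to_peak

    lo = 1e-12
    hi = tau_decay
    while f(hi) < 0:
        hi *= 2
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16))


def transient_kernel(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    """Unit-peak transient waveform; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    t_star = tau_r * math.log1p(tau_d / tau_r)
    g_peak = (1.0 - math.exp(-t_star / tau_r)) * math.exp(-t_star / tau_d)
    out = np.zeros_like(t)
    rise = (t >= 0) & (t <= t_star)
    out[rise] = (1.0 - np.exp(-t[rise] / tau_r)) * np.exp(-t[rise] / tau_d) / g_peak
    decay = t > t_star
    out[decay] = np.exp(-(t[decay] - t_star) / tau_d)
    return out


def kernel_max_rate(amplitude: float, tau_r: float, tau_d: float) -> float:
    """Max rate of rise of ``amplitude * g`` in signal units per ms."""
    t_star = tau_r * math.log1p(tau_d / tau_r)
    tt = np.linspace(0.0, t_star, 4001)
    g = transient_kernel(tt, tau_r, tau_d)
    return float(np.max(np.gradient(g, tt))) * amplitude / 1000.0
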