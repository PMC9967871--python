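"""Synthetic data with controllable ground truth for every analysis stage.

Each generator is a deterministic function of its (mandatory) seed and
returns both the synthetic object and a ground-truth record, so every
analyzer can be validated by parameter recovery without any external data.

Transient kernel
----------------
Each beat contributes ``amplitude * g(t - t_stim)`` where ``g`` rises as a
product of exponentials and decays *exactly* monoexponentially::

    g(t) = (1 - exp(-t/tau_r)) * exp(-t/tau_d) / g_peak   for t <= t*
    g(t) = exp(-(t - t*) / tau_d)                          for t >  t*

with the peak time ``t* = tau_r * ln(1 + tau_d/tau_r)`` of the rise
product.  ``tau_r`` is solved from the requested time-to-peak through that
closed relation.  The exactly exponential decay makes amplitude,
time-to-peak and decay tau independently well defined, so the fitted tau
is unbiased rather than contaminated by the rise term; superposed beat
tails share the same tau and therefore never bias the fit either.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .errors import AnalysisError, ValidationError
from .io import FluorescenceTrace, LabelImage, OxygraphEvent, OxygraphRecording
from .oxygraph import PsiCalibration, inverse_psi
from .waveform import kernel_max_rate, solve_rise_tau, transient_kernel

# ---------------------------------------------------------------------------
# transient traces


@dataclass(frozen=True)
class TransientGenSpec:
    """Ground-truth parameters of a paced synthetic recording.

    ``mode="ratiometric"`` emits Fura-2-like F340/F380 channels whose ratio
    reproduces the target signal exactly; ``mode="single"`` emits one
    Rhod-2-like channel ``F = f0 * (1 + signal)`` so that dF/F0 against the
    quiet pre-stimulus baseline recovers the target (diastolic is then in
    dF/F0 units and usually 0).  ``noise_sd`` is Gaussian, per sample, in
    signal units; photobleaching is the linear ``drift_per_s`` term.
    """

    seed: int
    diastolic: float = 1.0
    amplitude: float = 0.5
    time_to_peak_s: float = 0.08
    tau_decay_s: float = 0.27
    stim_freq_hz: float = 1.0
    n_beats: int = 20
    noise_sd: float = 0.0
    drift_per_s: float = 0.0
    sampling_rate_hz: float = 400.0
    mode: str = "ratiometric"
    pre_quiet_s: float = 1.0
    base_intensity_au: float = 2.0
    channel_split: float = 0.3  # anti-correlated modulation depth of F380
    f0_au: float = 5.0  # single-mode baseline intensity
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("ratiometric", "single"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.stim_freq_hz <= 0 or self.n_beats < 1:
            raise ValidationError("need stim_freq_hz > 0 and n_beats >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.channel_split < 1):
            raise ValidationError("channel_split must be in [0, 1)")
        solve_rise_tau(self.time_to_peak_s, self.tau_decay_s)  # validates reachability


def _clean_signal(spec: TransientGenSpec, time: np.ndarray, stims: np.ndarray):
    """Noise-free target signal and its normalized transient part."""
    tau_r = solve_rise_tau(spec.time_to_peak_s, spec.tau_decay_s)
    g_sum = np.zeros_like(time)
    for s in stims:
        i0 = int(np.searchsorted(time, s - 1e-12))
        g_sum[i0:] += transient_kernel(time[i0:] - s, tau_r, spec.tau_decay_s)
    signal = spec.diastolic + spec.amplitude * g_sum + spec.drift_per_s * time
    return signal, g_sum, tau_r


def gen_transient_trace(spec: TransientGenSpec) -> tuple[FluorescenceTrace, dict]:
    """Paced synthetic recording plus the exact ground truth used to build it."""
    dt = 1.0 / spec.sampling_rate_hz
    period = 1.0 / spec.stim_freq_hz
    n = int(round((spec.pre_quiet_s + spec.n_beats * period) / dt))
    time = np.arange(n) * dt
    stims = spec.pre_quiet_s + np.arange(spec.n_beats) * period
    clean, g_sum, tau_r = _clean_signal(spec, time, stims)

    rng = np.random.default_rng(spec.seed)
    signal = clean + rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else clean

    if spec.mode == "ratiometric":
        # F380 dips with the transient, F340 = ratio * F380 rises: the
        # computed ratio reproduces the (noisy) target signal exactly.
        f380 = spec.base_intensity_au * (1.0 - spec.channel_split * g_sum)
        channels = {"F340": signal * f380, "F380": f380}
        modality = "ratiometric"
    else:
        channels = {"F": spec.f0_au * (1.0 + signal)}
        modality = "single"

    trace = FluorescenceTrace(
        time=time,
        channels=channels,
        sampling_rate=spec.sampling_rate_hz,
        modality=modality,
        stim_freq=spec.stim_freq_hz,
        stim_times=stims,
        meta={**spec.meta, "synthetic": True},
    )
    truth = {
        "diastolic": spec.diastolic,
        "amplitude": spec.amplitude,
        "time_to_peak": spec.time_to_peak_s,
        "tau_decay": spec.tau_decay_s,
        "tau_rise": tau_r,
        "max_rate_of_rise": kernel_max_rate(spec.amplitude, tau_r, spec.tau_decay_s),
        "stim_times": [float(s) for s in stims],
        "stim_freq": spec.stim_freq_hz,
        "f0_window": (0.0, spec.pre_quiet_s),
        "mode": spec.mode,
        "seed": spec.seed,
    }
    return trace, truth


def gen_caffeine_trace(
    store_amplitude: float = 0.59,
    tau_efflux_s: float = 6.07,
    seed: int = 0,
    diastolic: float = 1.0,
    pre_s: float = 10.0,
    post_s: float = 40.0,
    ramp_s: float = 0.5,
    noise_sd: float = 0.0,
    sampling_rate_hz: float = 400.0,
    base_intensity_au: float = 2.0,
    channel_split: float = 0.3,
    meta: dict | None = None,
) -> tuple[FluorescenceTrace, dict]:
    """Unpaced caffeine-bolus transient: flat diastolic, a fixed linear ramp
    to ``diastolic + store_amplitude`` at the event, then monoexponential
    decay with ``tau_efflux_s`` back to diastolic."""
    if post_s < 3.0 * tau_efflux_s:
        warnings.warn(
            f"post-event record {post_s} s < 3 tau ({3 * tau_efflux_s:.1f} s): "
            "truncated decay biases the efflux fit",
            stacklevel=2,
        )
    dt = 1.0 / sampling_rate_hz
    n = int(round((pre_s + post_s) / dt))
    time = np.arange(n) * dt
    t_ev = pre_s
    t_peak = t_ev + ramp_s
    clean = np.full(n, float(diastolic))
    ramp = (time >= t_ev) & (time <= t_peak)
    clean[ramp] += store_amplitude * (time[ramp] - t_ev) / ramp_s
    decay = time > t_peak
    clean[decay] += store_amplitude * np.exp(-(time[decay] - t_peak) / tau_efflux_s)

    rng = np.random.default_rng(seed)
    signal = clean + rng.normal(0.0, noise_sd, n) if noise_sd else clean
    g_norm = (clean - diastolic) / store_amplitude
    f380 = base_intensity_au * (1.0 - channel_split * g_norm)
    trace = FluorescenceTrace(
        time=time,
        channels={"F340": signal * f380, "F380": f380},
        sampling_rate=sampling_rate_hz,
        modality="ratiometric",
        stim_freq=0.0,
        events=[("caffeine", float(t_ev))],
        meta={**(meta or {}), "synthetic": True},
    )
    truth = {
        "store_amplitude": store_amplitude,
        "tau_efflux": tau_efflux_s,
        "diastolic": diastolic,
        "caffeine_time": float(t_ev),
        "peak_time": float(t_peak),
        "seed": seed,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# oxygraph recordings


@dataclass(frozen=True)
class OxyStateSpec:
    """One protocol step: event label, duration, O2 slope and target psi."""

    label: str  # GMP | ADP_HEX | CACL2 | FCCP
    duration_s: float
    o2_slope_um_s: float
    psi_mv: float  # ignored (forced depolarised) for FCCP
    dose: str = ""


#: protocol of the respirometry assay: CI substrates, ADP + hexokinase,
#: one 0.3 mM CaCl2 bolus (free Ca2+ 0.39 uM), FCCP uncoupling
DEFAULT_OXY_PROTOCOL = (
    OxyStateSpec("GMP", 300.0, -0.010, -210.0),
    OxyStateSpec("ADP_HEX", 300.0, -0.050, -160.0),
    OxyStateSpec("CACL2", 300.0, -0.055, -150.0, dose="0.3"),
    OxyStateSpec("FCCP", 200.0, -0.060, 0.0),
)

#: externally supplied cumulative CaCl2 (mM) -> free [Ca2+] (uM)
DEFAULT_FREE_CA_LADDER = {0.3: 0.39}


@dataclass(frozen=True)
class OxygraphGenSpec:
    seed: int
    states: tuple[OxyStateSpec, ...] = DEFAULT_OXY_PROTOCOL
    calib: PsiCalibration = PsiCalibration()
    chamber_volume_ml: float = 2.0
    tissue_mass_mg: float = 2.0
    o2_start_um: float = 200.0
    sample_interval_s: float = 1.0
    noise_sd_o2: float = 0.0
    noise_sd_saf: float = 0.0
    free_ca_ladder: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if not labels or labels[0] != "GMP":
            raise ValidationError("protocol must start with GMP")
        order = {"GMP": 0, "ADP_HEX": 1, "CACL2": 2, "FCCP": 3}
        ranks = [order.get(l) for l in labels]
        if None in ranks or ranks != sorted(ranks) or labels.count("GMP") > 1:
            raise ValidationError(
                "states must follow the protocol order GMP -> ADP_HEX -> [CACL2...] -> FCCP"
            )
        for s in self.states:
            if s.label != "FCCP" and s.psi_mv > 0:
                raise ValidationError(f"energized state {s.label} requires psi <= 0 mV")


def gen_oxygraph(spec: OxygraphGenSpec) -> tuple[OxygraphRecording, dict]:
    """Piecewise-linear O2 course + per-state Nernstian safranine signal."""
    dt = spec.sample_interval_s
    total = sum(s.duration_s for s in spec.states)
    time = np.arange(0.0, total, dt)
    o2 = np.empty_like(time)
    saf = np.empty_like(time)
    events = []
    truth_states = []
    t0, o2_level = 0.0, spec.o2_start_um
    for s in spec.states:
        sel = (time >= t0 - dt / 2) & (time < t0 + s.duration_s - dt / 2)
        o2[sel] = o2_level + s.o2_slope_um_s * (time[sel] - t0)
        c_rb = spec.calib.c_fccp_um if s.label == "FCCP" else inverse_psi(s.psi_mv, spec.calib)
        saf[sel] = c_rb
        events.append(OxygraphEvent(label=s.label, time=t0, dose=s.dose))
        flux = -s.o2_slope_um_s * spec.chamber_volume_ml * 1000.0 / spec.tissue_mass_mg
        truth_states.append(
            {
                "label": s.label,
                "flux": flux,
                "psi": 0.0 if s.label == "FCCP" else s.psi_mv,
                "c_rb": c_rb,
                "o2_slope": s.o2_slope_um_s,
            }
        )
        o2_level += s.o2_slope_um_s * s.duration_s
        t0 += s.duration_s
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_o2:
        o2 = o2 + rng.normal(0.0, spec.noise_sd_o2, o2.size)
    if spec.noise_sd_saf:
        saf = saf + rng.normal(0.0, spec.noise_sd_saf, saf.size)
    rec = OxygraphRecording(
        time=time,
        o2_conc=np.clip(o2, 0.0, None),
        safranine=saf,
        events=events,
        chamber_volume_ml=spec.chamber_volume_ml,
        tissue_mass_mg=spec.tissue_mass_mg,
        free_ca_ladder=dict(spec.free_ca_ladder) if spec.free_ca_ladder else None,
        meta={**spec.meta, "synthetic": True},
    )
    truth = {"states": truth_states, "seed": spec.seed, "calib": vars(spec.calib).copy()}
    return rec, truth


# ---------------------------------------------------------------------------
# cluster images


@dataclass(frozen=True)
class ClusterImageGenSpec:
    """STED-like frame of labelled clusters with known positions and areas.

    Cluster areas are lognormal with the given mean (um^2) and log-space
    sigma; each cluster is rendered as a uniform disk of that area blurred
    by a Gaussian PSF (``psf_sigma_nm``), so its half-maximum contour
    encloses the ground-truth area.  ``spot_profile="gaussian"`` instead
    renders a Gaussian of FWHM = 2 sqrt(area/pi), adequate only for sparse
    fields.  Overlap policy "reject" resamples positions until all centre
    distances exceed ``min_sep_factor`` times the sum of the disk radii
    (largest spots placed first); "allow" skips the check.
    """

    seed: int
    frame_um: float = 15.0
    pixel_size_nm: float = 15.0
    density_per_um2: float = 11.2
    mean_area_um2: float = 0.034
    area_sigma: float = 0.5
    amplitude: float = 1.0
    background: float = 0.05
    noise_sd: float = 0.02
    spot_profile: str = "disk"
    psf_sigma_nm: float = 20.0
    min_sep_factor: float = 1.0
    overlap: str = "reject"
    n_spots: int | None = None
    margin_um: float = 0.0
    channel_label: str = "TOM20"
    max_attempts_per_spot: int = 1000
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density_per_um2 < 0 or self.mean_area_um2 <= 0:
            raise ValidationError("density must be >= 0 and mean area positive")
        if self.spot_profile not in ("disk", "gaussian"):
            raise ValidationError("spot_profile must be 'disk' or 'gaussian'")
        if self.overlap not in ("reject", "allow"):
            raise ValidationError("overlap must be 'reject' or 'allow'")


def _rsa_positions(
    rng: np.random.Generator,
    radii: np.ndarray,
    frame: float,
    margin: float,
    sep_factor: float,
    max_attempts_per_spot: int,
) -> np.ndarray:
    """Random sequential adsorption with per-pair minimum separation.

    Spots are placed largest-first (small spots fill interstices), using a
    uniform grid for neighbour lookups.
    """
    n = radii.size
    pos = np.empty((n, 2))
    if n == 0:
        return pos
    cell = max(2.0 * sep_factor * float(radii.max()), 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}
    lo, hi = margin, frame - margin
    if hi <= lo:
        raise ValidationError("margin leaves no room to place spots")
    budget = max_attempts_per_spot * n
    for i in range(n):
        for _ in range(max_attempts_per_spot):
            budget -= 1
            x, y = rng.uniform(lo, hi, 2)
            gx, gy = int(x / cell), int(y / cell)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for j in grid.get((gx + dx, gy + dy), ()):
                        d2 = (x - pos[j, 0]) ** 2 + (y - pos[j, 1]) ** 2
                        dmin = sep_factor * (radii[i] + radii[j])
                        if d2 < dmin * dmin:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pos[i] = (x, y)
                grid.setdefault((gx, gy), []).append(i)
                break
            if budget <= 0:
                break
        else:
            raise AnalysisError(
                f"requested density infeasible under min-separation: placed {i} of {n} spots"
            )
        if budget <= 0 and i < n - 1:
            raise AnalysisError(
                f"requested density infeasible under min-separation: placed {i + 1} of {n} spots"
            )
    return pos


def gen_cluster_image(spec: ClusterImageGenSpec) -> tuple[LabelImage, dict]:
    """Render a synthetic frame; ground truth lists every spot."""
    rng = np.random.default_rng(spec.seed)
    frame = spec.frame_um
    if spec.n_spots is not None:
        n = int(spec.n_spots)
    else:
        n = int(rng.poisson(spec.density_per_um2 * frame * frame))
    mu = math.log(spec.mean_area_um2) - spec.area_sigma**2 / 2.0
    areas = np.sort(rng.lognormal(mu, spec.area_sigma, n))[::-1]  # largest first
    radii = np.sqrt(areas / math.pi)
    if spec.overlap == "reject":
        pos = _rsa_positions(
            rng, radii, frame, spec.margin_um, spec.min_sep_factor, spec.max_attempts_per_spot
        )
    else:
        pos = rng.uniform(spec.margin_um, frame - spec.margin_um, (n, 2))

    s_um = spec.pixel_size_nm / 1000.0
    npx = int(round(frame / s_um))
    img = np.full((npx, npx), float(spec.background))
    sigma_psf = spec.psf_sigma_nm / 1000.0
    for (x, y), r in zip(pos, radii):
        if spec.spot_profile == "disk":
            reach = r + 4.0 * sigma_psf
        else:
            sigma_g = 2.0 * r / 2.3548200450309493  # FWHM = 2 sqrt(area/pi)
            reach = 4.0 * sigma_g
        c0 = max(int((x - reach) / s_um), 0)
        c1 = min(int((x + reach) / s_um) + 2, npx)
        r0 = max(int((y - reach) / s_um), 0)
        r1 = min(int((y + reach) / s_um) + 2, npx)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = (np.arange(c0, c1) + 0.5) * s_um
        ys = (np.arange(r0, r1) + 0.5) * s_um
        rho = np.hypot(xs[None, :] - x, ys[:, None] - y)
        if spec.spot_profile == "disk":
            patch = 0.5 * erfc((rho - r) / (math.sqrt(2.0) * sigma_psf))
        else:
            patch = np.exp(-(rho**2) / (2.0 * sigma_g**2))
        img[r0:r1, c0:c1] += spec.amplitude * patch
    if spec.noise_sd:
        img += rng.normal(0.0, spec.noise_sd, img.shape)

    image = LabelImage(
        pixels=img,
        pixel_size_nm=spec.pixel_size_nm,
        channel_label=spec.channel_label,
        meta={**spec.meta, "synthetic": True},
    )
    truth = {
        "n_spots": n,
        "x_um": pos[:, 0].tolist(),
        "y_um": pos[:, 1].tolist(),
        "area_um2": areas.tolist(),
        "density_per_um2": n / (frame * frame),
        "mean_area_um2": float(np.mean(areas)) if n else 0.0,
        "seed": spec.seed,
    }
    return image, truth
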