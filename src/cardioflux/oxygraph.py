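"""Respirometry: per-state O2 flux and safranine-O membrane potential.

An event-marked oxygraph recording is cut into respiratory states
(CI Leak after complex-I substrates, CI OXPHOS after ADP + hexokinase,
Ca2+-titration steps, FCCP uncoupling).  Per state the O2 flux is the
negative least-squares slope of chamber [O2] scaled to pmol s^-1 mg^-1,
and the mitochondrial membrane potential follows from the Nernstian
partitioning of the cationic dye safranine-O between buffer and matrix:

    dPsi = (R*T / z*F) * ln(C_out / C_in)
    C_out = C_RB
    C_in  = (C_FCCP - C_RB) * V_RB / V_mito

where C_RB is the dye concentration remaining in the respiration buffer,
C_FCCP the (non-mitochondrial-uptake-corrected) signal after uncoupling,
and V_mito the mitochondrial volume (3.1 uL per mg tissue).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ValidationError
from .io import OxygraphRecording

R_GAS = 8.314  # J mol^-1 K^-1
FARADAY = 96485.0  # C mol^-1

#: mitochondrial volume per mg of ventricular tissue, uL mg^-1
V_MITO_UL_PER_MG = 3.1


@dataclass(frozen=True)
class PsiCalibration:
    """Every symbol of the safranine-O Nernst calibration.

    Concentrations in uM, volumes V_RB in mL and V_mito in uL,
    temperature in K, valence z = +1 for safranine-O.
    """

    c_total_um: float = 2.0
    c_fccp_um: float = 1.8
    v_rb_ml: float = 2.0
    v_mito_ul: float = 6.2
    temperature_k: float = 310.15
    z: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.c_fccp_um <= self.c_total_um):
            raise ValidationError("require 0 < C_FCCP <= C_total")
        if self.v_rb_ml <= 0 or self.v_mito_ul <= 0 or self.temperature_k <= 0:
            raise ValidationError("V_RB, V_mito and T must be positive")

    @classmethod
    def from_tissue_mass(cls, tissue_mass_mg: float, **kwargs) -> "PsiCalibration":
        """V_mito = 3.1 uL/mg x tissue mass."""
        return cls(v_mito_ul=V_MITO_UL_PER_MG * tissue_mass_mg, **kwargs)

    @property
    def volume_ratio(self) -> float:
        """r = V_RB / V_mito (dimensionless)."""
        return self.v_rb_ml * 1000.0 / self.v_mito_ul

    @property
    def nernst_slope_mv(self) -> float:
        """RT/zF in mV (26.73 mV at 310.15 K, z=1)."""
        return R_GAS * self.temperature_k / (self.z * FARADAY) * 1000.0


@dataclass
class RespiratoryState:
    """One respiratory state: window, O2 flux, membrane potential."""

    label: str
    t_start: float
    t_end: float
    flux: float = math.nan  # pmol s^-1 mg^-1
    psi: float = math.nan  # mV
    free_ca_um: float | None = None
    steady: bool = True
    o2_rising: bool = False  # positive O2 slope beyond tolerance
    mptp: bool = False  # sustained safranine release during Ca titration


_STATE_LABELS = {"GMP": "CI_Leak", "ADP_HEX": "CI_OXPHOS", "FCCP": "FCCP"}


def segment_states(rec: OxygraphRecording, settle: float = 60.0) -> list[RespiratoryState]:
    """Window per event, starting ``settle`` s after it, ending at the next.

    The final state runs to the end of the record.  Missing GMP event or a
    settle longer than an inter-event gap is an error.
    """
    if settle < 0:
        raise ValidationError("settle must be >= 0")
    if not any(e.label == "GMP" for e in rec.events):
        raise AnalysisError("missing GMP event: cannot identify the CI Leak state")
    states = []
    n_ca = 0
    t_last = float(rec.time[-1])
    for i, ev in enumerate(rec.events):
        if ev.label == "CACL2":
            n_ca += 1
            label = f"Ca_titration_{n_ca}"
        else:
            label = _STATE_LABELS[ev.label]
        start = ev.time + settle
        end = rec.events[i + 1].time if i + 1 < len(rec.events) else t_last
        if start >= end:
            raise AnalysisError(
                f"empty state window for {label}: settle {settle} s exceeds the "
                f"gap before the next event"
            )
        states.append(RespiratoryState(label=label, t_start=start, t_end=end))
    return states


def compute_flux(
    rec: OxygraphRecording,
    t_start: float,
    t_end: float,
    mass_mg: float | None = None,
) -> float:
    """O2 flux over a window in pmol s^-1 mg^-1.

    flux = -slope([O2] uM/s) x chamber volume (mL) x 1000 / mass (mg).
    """
    mass = mass_mg if mass_mg is not None else rec.tissue_mass_mg
    sel = (rec.time >= t_start) & (rec.time < t_end)
    if int(sel.sum()) < 10:
        raise AnalysisError(f"flux window [{t_start}, {t_end}) has < 10 samples")
    slope = float(np.polyfit(rec.time[sel], rec.o2_conc[sel], 1)[0])
    return -slope * rec.chamber_volume_ml * 1000.0 / mass


def safranine_to_psi(c_rb_um: float, calib: PsiCalibration) -> float:
    """Membrane potential (mV) from the buffer safranine-O concentration."""
    if c_rb_um <= 0:
        raise ValidationError("C_RB must be positive")
    if c_rb_um >= calib.c_fccp_um:
        raise AnalysisError("no net mitochondrial safranine uptake (C_RB >= C_FCCP)")
    c_out = c_rb_um
    c_in = (calib.c_fccp_um - c_rb_um) * calib.volume_ratio
    return calib.nernst_slope_mv * math.log(c_out / c_in)


def inverse_psi(psi_mv: float, calib: PsiCalibration) -> float:
    """Buffer safranine-O concentration (uM) producing a given potential.

    Closed-form inversion of the Nernst relation; monotone decreasing in
    |psi|.  Only non-positive (energized or depolarised-to-zero) potentials
    are meaningful.
    """
    if psi_mv > 0:
        raise ValidationError("psi must be <= 0 for an energized or depolarised state")
    k = math.exp(psi_mv / calib.nernst_slope_mv)
    kr = k * calib.volume_ratio
    return calib.c_fccp_um * kr / (1.0 + kr)


def calibrate_safranine(raw: np.ndarray, raw_zero: float, raw_total: float, c_total_um: float) -> np.ndarray:
    """Two-point linear fluorescence-to-concentration calibration.

    ``raw_zero`` is the signal with no dye, ``raw_total`` the signal with
    ``c_total_um`` of dye present and no mitochondrial uptake.
    """
    if raw_total == raw_zero:
        raise ValidationError("degenerate calibration: raw_total equals raw_zero")
    return (np.asarray(raw, dtype=float) - raw_zero) * c_total_um / (raw_total - raw_zero)


def _cumulative_ca_mm(events) -> dict[float, float]:
    """Event time -> cumulative CaCl2 (mM) from CACL2 dose annotations."""
    total = 0.0
    out = {}
    for ev in events:
        if ev.label != "CACL2":
            continue
        m = re.match(r"([0-9.eE+-]+)", ev.dose or "")
        total += float(m.group(1)) if m else 0.0
        out[ev.time] = total
    return out


def analyze_oxygraph(
    rec: OxygraphRecording,
    calib: PsiCalibration,
    settle: float = 60.0,
    steady_tol: float = 0.1,
    mptp_slope_tol: float = 1e-3,
) -> list[RespiratoryState]:
    """Per-state flux and membrane potential for a full protocol.

    psi is computed from the mean safranine signal over the steady tail
    (last third) of each state; the FCCP state is 0 mV by definition.
    Ca-titration states are annotated with free [Ca2+] from the recording's
    ladder when available, and screened for mPTP opening (sustained
    safranine release back toward C_FCCP faster than ``mptp_slope_tol``
    uM/s).  ``steady_tol`` bounds |d(flux)/dt| (pmol s^-2 mg^-1) over the
    tail for the steady flag.
    """
    states = segment_states(rec, settle=settle)
    ca_cum = _cumulative_ca_mm(rec.events)
    ca_times = sorted(ca_cum)
    for st in states:
        st.flux = compute_flux(rec, st.t_start, st.t_end)
        sel = (rec.time >= st.t_start) & (rec.time < st.t_end)
        tw, o2w, safw = rec.time[sel], rec.o2_conc[sel], rec.safranine[sel]
        slope = float(np.polyfit(tw, o2w, 1)[0])
        st.o2_rising = slope > 1e-4

        tail = tw >= st.t_start + 2.0 * (st.t_end - st.t_start) / 3.0
        # steady: flux drift from the quadratic term of the tail O2 course
        if int(tail.sum()) >= 3:
            curv = float(np.polyfit(tw[tail], o2w[tail], 2)[0])
            dflux_dt = abs(2.0 * curv) * rec.chamber_volume_ml * 1000.0 / rec.tissue_mass_mg
            st.steady = dflux_dt < steady_tol
        if st.label == "FCCP":
            st.psi = 0.0  # depolarised by definition
        else:
            c_rb = float(np.mean(safw[tail] if tail.any() else safw))
            try:
                st.psi = safranine_to_psi(c_rb, calib)
            except (AnalysisError, ValidationError):
                st.psi = math.nan
        if st.label.startswith("Ca_titration"):
            ev_time = max((t for t in ca_times if t <= st.t_start), default=None)
            if ev_time is not None and rec.free_ca_ladder:
                cum = ca_cum[ev_time]
                key = min(rec.free_ca_ladder, key=lambda k: abs(k - cum))
                if math.isclose(key, cum, rel_tol=1e-6, abs_tol=1e-9):
                    st.free_ca_um = rec.free_ca_ladder[key]
            saf_slope = float(np.polyfit(tw, safw, 1)[0])
            st.mptp = saf_slope > mptp_slope_tol
    return states
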