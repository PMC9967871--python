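"""Respirometry: flux arithmetic and the safranine-O Nernst calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardioflux as cf
from cardioflux.errors import AnalysisError, ValidationError


def _rec(slope=-0.01, volume=2.0, mass=2.0, n=600):
    t = np.arange(float(n))
    return cf.OxygraphRecording(
        time=t, o2_conc=200.0 + slope * t, safranine=np.full(n, 0.5),
        events=[cf.OxygraphEvent("GMP", 0.0)],
        chamber_volume_ml=volume, tissue_mass_mg=mass,
    )


CALIB = cf.PsiCalibration(c_total_um=2.0, c_fccp_um=2.0, v_rb_ml=2.0, v_mito_ul=6.2)


class TestFlux:
    def test_unit_arithmetic_fixture(self):
        # -0.01 uM/s, 2 mL chamber, 2 mg tissue -> 10 pmol s^-1 mg^-1
        assert cf.compute_flux(_rec(), 0.0, 600.0) == pytest.approx(10.0, rel=1e-12)

    def test_zero_slope_zero_flux(self):
        assert cf.compute_flux(_rec(slope=0.0), 0.0, 600.0) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_volume_inverse_in_mass(self):
        f = cf.compute_flux(_rec(), 0.0, 600.0)
        assert cf.compute_flux(_rec(volume=4.0), 0.0, 600.0) == pytest.approx(2 * f, rel=1e-12)
        assert cf.compute_flux(_rec(mass=4.0), 0.0, 600.0) == pytest.approx(f / 2, rel=1e-12)

    def test_noisy_slope_recovered_within_two_percent(self):
        spec = cf.OxygraphGenSpec(seed=9, noise_sd_o2=0.2)
        rec, truth = cf.gen_oxygraph(spec)
        states = cf.analyze_oxygraph(rec, spec.calib)
        for st_, t in zip(states, truth["states"]):
            assert st_.flux == pytest.approx(t["flux"], rel=0.02)


class TestSegmentStates:
    def test_windows_start_after_settle(self):
        spec = cf.OxygraphGenSpec(seed=0)
        rec, _ = cf.gen_oxygraph(spec)
        states = cf.segment_states(rec, settle=60.0)
        starts = [s.t_start for s in states]
        ends = [s.t_end for s in states]
        assert starts == [60.0, 360.0, 660.0, 960.0]
        assert ends[:3] == [300.0, 600.0, 900.0]
        assert [s.label for s in states] == ["CI_Leak", "CI_OXPHOS", "Ca_titration_1", "FCCP"]

    def test_settle_longer_than_gap_names_state(self):
        rec, _ = cf.gen_oxygraph(cf.OxygraphGenSpec(seed=0))
        with pytest.raises(AnalysisError, match="CI_Leak"):
            cf.segment_states(rec, settle=400.0)

    def test_missing_gmp_event(self):
        rec = _rec()
        rec.events = []
        with pytest.raises(AnalysisError, match="GMP"):
            cf.segment_states(rec)


class TestNernst:
    def test_worked_example(self):
        # C_FCCP 2 uM, C_RB 0.5 uM, 2 mL buffer, 6.2 uL mito volume, 37 C
        assert cf.safranine_to_psi(0.5, CALIB) == pytest.approx(-183.8, abs=0.1)

    def test_zero_potential_at_equal_concentrations(self):
        r = CALIB.volume_ratio
        c_rb = CALIB.c_fccp_um * r / (1 + r)
        assert cf.safranine_to_psi(c_rb, CALIB) == pytest.approx(0.0, abs=1e-12)
        assert cf.inverse_psi(0.0, CALIB) == pytest.approx(c_rb, rel=1e-12)

    def test_decade_step_is_61_5_mv(self):
        # tenfold change in C_out/C_in at 310.15 K
        assert CALIB.nernst_slope_mv * math.log(10) == pytest.approx(61.5, abs=0.1)

    def test_monotone_in_c_rb(self):
        grid = np.linspace(1e-4, CALIB.c_fccp_um * 0.999, 200)
        psi = np.array([cf.safranine_to_psi(c, CALIB) for c in grid])
        assert np.all(np.diff(psi) > 0)  # toward 0 as C_RB grows

    def test_volume_ratio_dimensionless(self):
        doubled = cf.PsiCalibration(
            c_total_um=2.0, c_fccp_um=2.0, v_rb_ml=4.0, v_mito_ul=12.4
        )
        assert cf.safranine_to_psi(0.5, doubled) == pytest.approx(
            cf.safranine_to_psi(0.5, CALIB), rel=1e-12
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(psi=st.floats(min_value=-250.0, max_value=0.0))
    def test_inverse_roundtrip(self, psi):
        assert cf.safranine_to_psi(cf.inverse_psi(psi, CALIB), CALIB) == pytest.approx(
            psi, abs=1e-9
        )

    def test_inverse_at_leak_potential_matches_bisection(self):
        target = -210.0
        c = cf.inverse_psi(target, CALIB)
        lo, hi = 1e-9, CALIB.c_fccp_um * CALIB.volume_ratio / (1 + CALIB.volume_ratio)
        for _ in range(200):  # bracketed bisection on the Nernst relation
            mid = (lo + hi) / 2
            if cf.safranine_to_psi(mid, CALIB) < target:
                lo = mid
            else:
                hi = mid
        assert c == pytest.approx((lo + hi) / 2, rel=1e-9)
        assert cf.safranine_to_psi(c, CALIB) == pytest.approx(target, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(AnalysisError, match="no net mitochondrial"):
            cf.safranine_to_psi(CALIB.c_fccp_um, CALIB)
        with pytest.raises(ValidationError):
            cf.safranine_to_psi(0.0, CALIB)
        with pytest.raises(ValidationError):
            cf.inverse_psi(5.0, CALIB)

    def test_two_point_calibration(self):
        raw = np.array([10.0, 55.0, 100.0])
        out = cf.calibrate_safranine(raw, raw_zero=10.0, raw_total=100.0, c_total_um=2.0)
        np.testing.assert_allclose(out, [0.0, 1.0, 2.0], atol=1e-12)


class TestAnalyzeOxygraph:
    def test_noiseless_protocol_recovered_exactly(self):
        spec = cf.OxygraphGenSpec(seed=0, free_ca_ladder={0.3: 0.39})
        rec, truth = cf.gen_oxygraph(spec)
        states = cf.analyze_oxygraph(rec, spec.calib)
        for st_, t in zip(states, truth["states"]):
            assert st_.flux == pytest.approx(t["flux"], rel=1e-9)
            assert st_.psi == pytest.approx(t["psi"], abs=1e-6)
            assert st_.steady
        assert states[-1].label == "FCCP" and states[-1].psi == 0.0
        assert states[2].free_ca_um == pytest.approx(0.39)

    def test_missing_ladder_leaves_free_ca_unknown(self):
        spec = cf.OxygraphGenSpec(seed=0)
        rec, _ = cf.gen_oxygraph(spec)
        states = cf.analyze_oxygraph(rec, spec.calib)
        assert states[2].free_ca_um is None
        assert all(math.isfinite(s.flux) for s in states)

    def test_mptp_opening_detected(self):
        spec = cf.OxygraphGenSpec(seed=0)
        rec, _ = cf.gen_oxygraph(spec)
        # sustained safranine release toward C_FCCP during the Ca step
        sel = (rec.time >= 600) & (rec.time < 900)
        rec.safranine[sel] += np.linspace(0.0, 0.9, int(sel.sum()))
        states = cf.analyze_oxygraph(rec, spec.calib)
        ca = [s for s in states if s.label.startswith("Ca_titration")][0]
        assert ca.mptp
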