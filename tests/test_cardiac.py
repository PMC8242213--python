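"""Ventricular mechanics: pressure law, sarcomere map, stress laws, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiorenal.cardiac import (
    active_stress,
    extract_beat_summary,
    passive_stress,
    sarcomere_kinematics,
    ventricular_pressure,
)


class TestVentricularPressure:
    def test_closed_form_value(self):
        # 49.2 kPa fiber stress, no radial stress, wall 120 mL, cavity 103 mL
        p = ventricular_pressure(49.2, 0.0, 120.0, 103.0)
        assert p == pytest.approx(49.2 / 3.0 * math.log(1.0 + 120.0 / 103.0), rel=1e-14)
        assert p == pytest.approx(12.67, abs=0.01)

    def test_stress_term_vanishes(self):
        assert ventricular_pressure(10.0, 5.0, 120.0, 103.0) == 0.0

    def test_vanishing_wall(self):
        assert ventricular_pressure(50.0, 0.0, 1e-12, 103.0) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("vw,vcav", [(0.0, 100.0), (120.0, 0.0), (-5.0, 100.0)])
    def test_domain_errors(self, vw, vcav):
        with pytest.raises(ValueError):
            ventricular_pressure(50.0, 0.0, vw, vcav)

    @settings(max_examples=200, deadline=None)
    @given(
        sf=st.floats(0.0, 100.0), smr=st.floats(-10.0, 10.0),
        vw=st.floats(1.0, 400.0), v=st.floats(1.0, 400.0),
    )
    def test_matches_direct_formula(self, sf, smr, vw, v):
        expected = (sf - 2.0 * smr) / 3.0 * math.log(1.0 + vw / v)
        assert ventricular_pressure(sf, smr, vw, v) == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestSarcomereKinematics:
    def test_reference_point(self):
        l_s, eps = sarcomere_kinematics(52.0, 52.0, 120.0)
        assert l_s == pytest.approx(2.0)
        assert eps == pytest.approx(0.0)

    def test_monotone_in_cavity_volume(self):
        lengths = [sarcomere_kinematics(v, 52.0, 120.0)[0] for v in np.linspace(20, 300, 40)]
        assert np.all(np.diff(lengths) > 0)

    def test_cube_root_scaling_of_effective_volume(self):
        # doubling the effective volume V + Vw/3 scales l_s by 2**(1/3)
        vw = 120.0
        v1 = 100.0
        v2 = 2.0 * (v1 + vw / 3.0) - vw / 3.0
        l1, _ = sarcomere_kinematics(v1, 52.0, vw)
        l2, _ = sarcomere_kinematics(v2, 52.0, vw)
        assert l2 / l1 == pytest.approx(2.0 ** (1.0 / 3.0), rel=1e-12)

    def test_strain_is_derivative_consistent(self):
        # finite difference of the volume -> stretch map matches d(eps)/dV
        vw, v0, v = 120.0, 52.0, 140.0
        h = 1e-4
        eps_p = sarcomere_kinematics(v + h, v0, vw)[1]
        eps_m = sarcomere_kinematics(v - h, v0, vw)[1]
        analytic = 1.0 / (3.0 * (v + vw / 3.0))
        assert (eps_p - eps_m) / (2 * h) == pytest.approx(analytic, rel=1e-6)

    def test_rejects_nonpositive_volumes(self):
        with pytest.raises(ValueError):
            sarcomere_kinematics(-1.0, 52.0, 120.0)


class TestActiveStress:
    kw = dict(sigma_a0=100.0, cycle_length=60.0 / 70.0)

    def test_zero_in_diastole(self):
        assert active_stress(2.2, 0.8, 0.0, **self.kw) == 0.0

    def test_zero_below_zero_force_length(self):
        assert active_stress(1.2, 0.15, 0.0, l_s_zero=1.51, **self.kw) == 0.0

    def test_nonnegative_and_bounded(self):
        for t in np.linspace(0.0, 0.85, 40):
            s = active_stress(2.1, t, 0.0, **self.kw)
            assert 0.0 <= s <= 100.0

    def test_shortening_reduces_force(self):
        resting = active_stress(2.1, 0.15, 0.0, **self.kw)
        shortening = active_stress(2.1, 0.15, -5.0, v_max=10.0, **self.kw)
        assert shortening < resting

    def test_ceiling_saturates_smoothly(self):
        unsat = active_stress(2.2, 0.15, 0.0, **self.kw)
        sat = active_stress(2.2, 0.15, 0.0, sigma_act_max=60.0, sigma_act_knee=40.0, **self.kw)
        assert sat < unsat
        assert sat < 60.0

    def test_rejects_time_outside_cycle(self):
        with pytest.raises(ValueError):
            active_stress(2.1, 1.0, 0.0, **self.kw)


class TestPassiveStress:
    def test_zero_at_unloaded_length(self):
        assert passive_stress(2.0, l_s_unloaded=2.0) == 0.0
        assert passive_stress(1.8, l_s_unloaded=2.0) == 0.0

    def test_monotone(self):
        xs = np.linspace(2.0, 2.6, 30)
        ys = [passive_stress(x) for x in xs]
        assert np.all(np.diff(ys) >= 0)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            passive_stress(0.0)


def _square_wave_trace():
    hr = 70.0
    cycle = 60.0 / hr
    t = np.linspace(0.0, cycle, 3001)
    p_art = np.where(t < cycle / 3.0, 113.0, 71.0)
    v_lv = 103.0 - 71.0 * np.sin(np.pi * t / cycle) ** 2
    return pd.DataFrame({
        "time_s": t, "P_art": p_art, "P_lv": p_art * 0.9,
        "V_lv": v_lv, "sigma_f": np.full_like(t, 10.0),
    }), hr


class TestExtractBeatSummary:
    def test_constant_pressure_gives_map(self):
        hr = 70.0
        t = np.linspace(0.0, 60.0 / hr, 500)
        df = pd.DataFrame({
            "time_s": t, "P_art": np.full_like(t, 90.0), "P_lv": np.full_like(t, 50.0),
            "V_lv": 103.0 - 10 * t, "sigma_f": np.full_like(t, 5.0),
        })
        assert extract_beat_summary(df, hr).MAP == pytest.approx(90.0)

    def test_square_wave_map(self):
        df, hr = _square_wave_trace()
        # 113 mmHg for a third of the cycle, 71 for the rest
        assert extract_beat_summary(df, hr).MAP == pytest.approx(85.0, abs=0.1)

    def test_stroke_volume_and_ejection_fraction(self):
        df, hr = _square_wave_trace()
        s = extract_beat_summary(df, hr)
        assert s.EDV == pytest.approx(103.0, abs=0.01)
        assert s.ESV == pytest.approx(32.0, abs=0.01)
        assert s.SV == pytest.approx(71.0, abs=0.02)
        assert s.EF == pytest.approx(71.0 / 103.0, abs=1e-3)

    def test_rejects_short_trace(self):
        df, hr = _square_wave_trace()
        with pytest.raises(ValueError):
            extract_beat_summary(df.iloc[:100], hr)

    def test_rejects_missing_columns(self):
        df, hr = _square_wave_trace()
        with pytest.raises(ValueError):
            extract_beat_summary(df.drop(columns=["P_art"]), hr)
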