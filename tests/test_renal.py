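"""Renal network: hemodynamics, filtration, tubular handling, body fluids."""

import pytest

from cardiorenal.renal import (
    BodyFluidState,
    RenalBaseline,
    RenalParams,
    fluid_balance,
    glomerular_filtration,
    renal_hemodynamics,
    renal_operating_point,
    sodium_handling,
    water_handling,
)

P = RenalParams()
BASE = RenalBaseline.from_params(P)


class TestBaselineClosure:
    """With every signal at 1 and MAP at its setpoint, the kidney delivers
    exactly its nominal flows and excretion equals intake by construction."""

    def test_hemodynamics(self):
        v = renal_hemodynamics(P.MAP0, P.P_ven0, P, BASE)
        assert v.RBF == pytest.approx(1.0, rel=1e-12)
        assert v.P_gc == pytest.approx(BASE.P_gc0, rel=1e-12)
        assert v.RIHP == pytest.approx(P.RIHP0, rel=1e-9)

    def test_filtration(self):
        v = renal_hemodynamics(P.MAP0, P.P_ven0, P, BASE)
        gfr = glomerular_filtration(v.P_gc, P.P_bowman, P.pi_gc, BASE.K_f)
        assert gfr == pytest.approx(P.GFR0, rel=1e-12)

    def test_operating_point_balances_intake(self):
        rs = renal_operating_point(P.MAP0, P.P_ven0, P.c_na0, P, BASE)
        assert rs.nephron.na_excretion == pytest.approx(P.na_intake0, rel=1e-9)
        assert rs.nephron.urine_flow == pytest.approx(P.water_intake0, rel=1e-9)
        assert rs.mu_tgf == pytest.approx(1.0, abs=1e-9)
        assert rs.mu_myo == pytest.approx(1.0, abs=1e-9)


class TestHemodynamics:
    def test_afferent_constriction_lowers_gfr_inputs(self):
        ref = renal_hemodynamics(P.MAP0, P.P_ven0, P, BASE)
        constricted = renal_hemodynamics(P.MAP0, P.P_ven0, P, BASE, mu_tgf=2.0)
        assert constricted.RBF < ref.RBF
        assert constricted.P_gc < ref.P_gc

    def test_at1_raises_glomerular_pressure_at_lower_flow(self):
        # efferent-dominant constriction by AT1-bound AngII
        ref = renal_hemodynamics(P.MAP0, P.P_ven0, P, BASE)
        ang = renal_hemodynamics(P.MAP0, P.P_ven0, P, BASE, at1=1.8)
        assert ang.RBF < ref.RBF
        assert ang.P_gc > ref.P_gc

    def test_requires_positive_perfusion_gradient(self):
        with pytest.raises(ValueError):
            renal_hemodynamics(2.0, 5.0, P, BASE)


class TestFiltration:
    def test_zero_at_zero_net_pressure(self):
        assert glomerular_filtration(46.0, 18.0, 28.0, BASE.K_f) == 0.0

    def test_clamped_at_zero(self):
        assert glomerular_filtration(30.0, 18.0, 28.0, BASE.K_f) == 0.0

    def test_arithmetic(self):
        assert glomerular_filtration(71.0, 18.0, 28.0, 4.0) == pytest.approx(100.0)

    def test_rejects_bad_coefficient(self):
        with pytest.raises(ValueError):
            glomerular_filtration(60.0, 18.0, 28.0, 0.0)


class TestSodiumHandling:
    filtered0 = P.GFR0 * P.c_na0 / 1000.0

    def test_baseline_balance(self):
        *_, excretion = sodium_handling(self.filtered0, P, BASE)
        assert excretion == pytest.approx(P.na_intake0, rel=1e-12)

    def test_zero_load_zero_excretion(self):
        *_, excretion = sodium_handling(0.0, P, BASE)
        assert excretion == 0.0

    def test_at1_blockade_reduces_proximal_reabsorption(self):
        f_pt_ref, *_ = sodium_handling(self.filtered0, P, BASE, at1=1.0)
        f_pt_blk, _, _, exc_blk = sodium_handling(self.filtered0, P, BASE, at1=0.4)
        assert f_pt_blk < f_pt_ref
        assert exc_blk > P.na_intake0  # natriuresis at fixed load

    def test_fractions_stay_in_unit_interval(self):
        f_pt, f_cd, *_ = sodium_handling(self.filtered0, P, BASE, at1=5.0, rihp_norm=0.1)
        assert 0.0 <= f_pt <= 1.0 and 0.0 <= f_cd <= 1.0

    def test_rejects_negative_load(self):
        with pytest.raises(ValueError):
            sodium_handling(-1.0, P, BASE)


class TestWaterHandling:
    def test_baseline_balance(self):
        assert water_handling(P.GFR0, P.f_pt0, P, BASE) == pytest.approx(P.water_intake0, rel=1e-12)

    def test_vasopressin_reduces_urine(self):
        low = water_handling(P.GFR0, P.f_pt0, P, BASE, vasopressin=1.5)
        high = water_handling(P.GFR0, P.f_pt0, P, BASE, vasopressin=0.5)
        assert low < P.water_intake0 < high

    def test_zero_gfr_zero_urine(self):
        assert water_handling(0.0, P.f_pt0, P, BASE) == 0.0

    def test_obligate_minimum(self):
        assert water_handling(P.GFR0, P.f_pt0, P, BASE, vasopressin=5.0) >= P.urine_min


class TestFluidBalance:
    def state(self):
        return BodyFluidState(body_na=BASE.body_na0, V_ecf=BASE.V_ecf0)

    def test_balanced_is_stationary(self):
        s2, vb = fluid_balance(self.state(), P.na_intake0, P.na_intake0,
                               P.water_intake0, P.water_intake0, 60.0, P, BASE)
        assert s2.body_na == pytest.approx(BASE.body_na0)
        assert vb == pytest.approx(P.V_b0)

    def test_baseline_partition(self):
        s = self.state()
        assert s.blood_volume(P, BASE) == pytest.approx(4.95)
        assert s.interstitial_volume(P, BASE) == pytest.approx(12.0)
        assert s.plasma_na() == pytest.approx(140.0)

    def test_one_day_retention_accumulates_1_44_litres(self):
        # +1 mL/min net water for 24 h -> +1.44 L ECF, split by the
        # compliance slope between blood and interstitium
        s2, vb = fluid_balance(self.state(), P.na_intake0, P.na_intake0,
                               P.water_intake0 + 1.0, P.water_intake0, 1440.0, P, BASE)
        assert s2.V_ecf - BASE.V_ecf0 == pytest.approx(1.44, rel=1e-12)
        assert vb - P.V_b0 == pytest.approx(P.s_bv * 1.44, rel=1e-12)
        assert s2.interstitial_volume(P, BASE) - 12.0 == pytest.approx((1 - P.s_bv) * 1.44, rel=1e-9)

    def test_depletion_to_nonpositive_volume_is_hard_error(self):
        with pytest.raises(FloatingPointError):
            fluid_balance(self.state(), 0.0, 0.0, 0.0, 20.0, 1e6, P, BASE)


class TestOperatingPointResponses:
    def test_pressure_natriuresis_direction(self):
        # +10 mmHg renal perfusion raises sodium excretion
        ref = renal_operating_point(P.MAP0, P.P_ven0, P.c_na0, P, BASE)
        high = renal_operating_point(P.MAP0 + 10.0, P.P_ven0, P.c_na0, P, BASE)
        assert high.nephron.na_excretion > ref.nephron.na_excretion
        assert high.rihp_norm > ref.rihp_norm

    def test_venous_congestion_reduces_renal_blood_flow(self):
        ref = renal_operating_point(P.MAP0, P.P_ven0, P.c_na0, P, BASE)
        congested = renal_operating_point(P.MAP0, P.P_ven0 + 8.0, P.c_na0, P, BASE)
        assert congested.vasc.RBF < ref.vasc.RBF

    def test_congestive_hypotension_is_retentive(self):
        # the failing-circulation pattern — venous pressure up, arterial
        # pressure down — cuts sodium excretion below intake
        ref = renal_operating_point(P.MAP0, P.P_ven0, P.c_na0, P, BASE)
        failing = renal_operating_point(P.MAP0 - 8.0, P.P_ven0 + 8.0, P.c_na0, P, BASE)
        assert failing.nephron.na_excretion < ref.nephron.na_excretion
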