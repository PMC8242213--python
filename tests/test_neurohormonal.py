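"""RAAS cascade, ANP/vasopressin, and the intrinsic feedback signals."""

import numpy as np
import pytest

from cardiorenal.neurohormonal import (
    RAASParams,
    SignalParams,
    aldosterone_mr,
    angiotensin_cascade,
    anp_signal,
    bounded_effect,
    intrinsic_signals,
    raas_derivatives,
    raas_steady_state,
    renin_secretion,
    vasopressin_signal,
)

RP = RAASParams()


class TestBaselineFixedPoint:
    """Every operation returns 1 when its inputs are at their setpoints."""

    def test_renin(self):
        assert renin_secretion(1.0, 1.0, 0.0) == pytest.approx(1.0)

    def test_cascade(self):
        assert angiotensin_cascade(1.0) == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_aldosterone(self):
        ald, mr = aldosterone_mr(1.0)
        assert ald == pytest.approx(1.0) and mr == pytest.approx(1.0)

    def test_anp_and_vasopressin(self):
        assert anp_signal(1.0) == pytest.approx(1.0)
        assert vasopressin_signal(1.0) == pytest.approx(1.0)

    def test_intrinsic_signals(self):
        s = intrinsic_signals(1.0, 1.0, 1.0, 1.0)
        assert (s.TGF, s.myogenic, s.pressure_natriuresis) == pytest.approx((1.0, 1.0, 1.0))

    def test_closed_loop_steady_state(self):
        st = raas_steady_state(1.0)
        assert st.PRA == pytest.approx(1.0, abs=1e-9)
        assert st.AT1_AngII == pytest.approx(1.0, abs=1e-9)


class TestReninSecretion:
    def test_decreasing_in_macula_densa_flow(self):
        assert renin_secretion(1.3, 1.0, 0.0) < 1.0 < renin_secretion(0.7, 1.0, 0.0)

    def test_disinhibition_when_at1_falls(self):
        assert renin_secretion(1.0, 0.5, 0.0) > 1.0

    def test_secretion_cap(self):
        assert renin_secretion(0.5, 0.0, 0.0) <= RP.secretion_cap * (1 + RP.g_md)

    def test_inhibition_scaling(self):
        assert renin_secretion(1.0, 1.0, 0.75) == pytest.approx(0.25)

    def test_invalid_inhibition(self):
        with pytest.raises(ValueError):
            renin_secretion(1.0, 1.0, 1.5)


class TestClosedLoopNonlinearity:
    """The map from secretion inhibition to steady-state PRA reduction is
    strongly concave: blocking most of secretion removes far less activity
    because falling AT1-bound AngII disinhibits the remaining secretion."""

    def test_90_percent_inhibition_gives_about_40_percent_pra_drop(self):
        st = raas_steady_state(1.0, inhibition_fraction=0.90)
        assert 0.30 <= 1.0 - st.PRA <= 0.50

    def test_feedback_compensates_partial_inhibition(self):
        # the reduction in activity always lags the secretion block, most
        # strongly for partial blocks, and grows monotonically with it
        red = [1.0 - raas_steady_state(1.0, inhibition_fraction=i).PRA
               for i in (0.0, 0.45, 0.90)]
        assert red[0] == pytest.approx(0.0, abs=1e-9)
        assert 0.0 < red[1] < 0.45
        assert red[1] < red[2] < 0.90

    def test_at1_blockade_raises_prc_but_lowers_bound_fraction(self):
        st = raas_steady_state(1.0, at1_block_fraction=0.92)
        assert st.PRC > 1.0
        assert st.AT1_AngII < 1.0

    def test_no_renin_no_angiotensin(self):
        assert angiotensin_cascade(0.0) == pytest.approx((0.0, 0.0, 0.0, 0.0))


class TestHormoneShapes:
    def test_aldosterone_monotone_in_at1(self):
        lows = [aldosterone_mr(x)[0] for x in np.linspace(0.2, 3.0, 20)]
        assert np.all(np.diff(lows) >= 0)

    def test_mr_occupancy_saturates(self):
        ald_hi, mr_hi = aldosterone_mr(5.0)
        assert mr_hi < 2.0  # saturating form caps below twice baseline

    def test_anp_rises_with_filling(self):
        assert anp_signal(1.5) > 1.0 > anp_signal(0.7)

    def test_anp_clamped(self):
        sp = SignalParams()
        assert anp_signal(50.0) == sp.anp_max
        assert anp_signal(-50.0) == sp.anp_min

    def test_vasopressin_steep_in_plasma_na(self):
        assert vasopressin_signal(1.01) > 1.05

    def test_positivity_under_extreme_inputs(self):
        for x in (0.01, 0.5, 2.0, 100.0):
            assert renin_secretion(x, x, 0.0) > 0.0
            assert aldosterone_mr(x)[0] > 0.0
            assert bounded_effect(x, 0.9, 3.0) > 0.0


class TestIntrinsicSignalDirections:
    def test_tgf_constricts_on_high_distal_delivery(self):
        assert intrinsic_signals(1.2, 1.0, 1.0, 1.0).TGF > 1.0

    def test_myogenic_constricts_on_pressure(self):
        assert intrinsic_signals(1.0, 1.15, 1.0, 1.0).myogenic > 1.0

    def test_autoregulation_constricts_on_high_output(self):
        assert intrinsic_signals(1.0, 1.0, 1.0, 1.1).whole_body_autoreg > 1.0


class TestFirstOrderKinetics:
    def test_derivatives_vanish_at_steady_state(self):
        st = raas_steady_state(1.0)
        d = raas_derivatives(st, 1.0)
        assert all(abs(x) < 1e-9 for x in d)

    def test_relaxation_direction(self):
        st = raas_steady_state(1.0)
        st.PRC = 2.0  # perturb above steady state
        d_prc, *_ = raas_derivatives(st, 1.0)
        assert d_prc < 0.0
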