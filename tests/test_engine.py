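"""Engine behavior: coupling law, initialization, beat periodicity,
kernel/library consistency, interventions, outputs."""

import math

import numpy as np
import pandas as pd
import pytest

from cardiorenal import (
    InterventionEffect,
    InterventionSchedule,
    apply_intervention,
    venous_coupling,
)
from cardiorenal.cardiac import extract_beat_summary, passive_stress, sarcomere_kinematics
from cardiorenal.engine import atenolol_effects, losartan_effects
from cardiorenal.io import write_outputs
from cardiorenal.units import KPA_PER_MMHG


class TestVenousCoupling:
    def test_equilibrium(self):
        assert venous_coupling(3000.0, 3000.0, 5.0, 5.0, 1.0) == 0.0

    def test_relaxation_toward_target(self):
        # 10 mL below target at 1/min with balanced flows -> +10 mL/min
        assert venous_coupling(2990.0, 3000.0, 5.0, 5.0, 1.0) == pytest.approx(10.0)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            venous_coupling(3000.0, 3000.0, 5.0, 5.0, 0.0)


class TestInterventions:
    def test_linear_ramp(self):
        e = InterventionEffect("r_art_mult", 3.0, start_day=10.0, ramp_days=100.0)
        assert e.value(0.0) == 1.0
        assert e.value(60.0) == pytest.approx(2.0)
        assert e.value(200.0) == 3.0

    def test_explicit_start_value(self):
        e = InterventionEffect("dp_leak_kpa", 12.5, ramp_days=100.0, from_value=17.5)
        assert e.value(0.0) == 17.5
        assert e.value(50.0) == pytest.approx(15.0)

    def test_schedule_composition(self):
        sch = InterventionSchedule(atenolol_effects())
        assert sch.value("hr_delta", 10.0, 70.0) == pytest.approx(62.0)
        assert sch.value("renin_inhib", 10.0, 0.0) == pytest.approx(0.90)

    def test_losartan_preset(self):
        sch = InterventionSchedule(losartan_effects())
        assert sch.value("at1_block", 1.0, 0.0) == pytest.approx(0.92)

    def test_apply_intervention_returns_new_schedule(self):
        sch = InterventionSchedule()
        sch2 = apply_intervention(sch, InterventionEffect("na_intake_mult", 2.0))
        assert not sch.effects and len(sch2.effects) == 1

    def test_noop_effect_changes_nothing(self):
        sch = InterventionSchedule([InterventionEffect("hr_delta", 0.0)])
        assert sch.value("hr_delta", 5.0, 70.0) == 70.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            InterventionEffect("magic", 1.0)


class TestInitialization:
    def test_deterministic_and_idempotent(self, model, baseline_state):
        again = model.initialize_steady_state()
        assert np.allclose(again.y, baseline_state.y, rtol=1e-9)
        assert again.slow.fluids.V_ecf == pytest.approx(baseline_state.slow.fluids.V_ecf, rel=1e-9)

    def test_growth_signals_are_zero_at_baseline(self, model, baseline_summary):
        from cardiorenal.remodeling import diameter_growth_rate, length_growth_rate
        rp = model.remodel_params
        # peak stress sits at its setpoint, ED stress below its threshold
        assert abs(diameter_growth_rate(baseline_summary.sigma_f_peak, rp, 0.0)) < 0.02
        assert length_growth_rate(baseline_summary.sigma_f_ED, rp, 0.0) == 0.0

    def test_regulatory_signals_at_setpoint(self, baseline_slow_point):
        renal_state, raas, anp, vp = baseline_slow_point
        assert renal_state.mu_tgf == pytest.approx(1.0, abs=1e-3)
        assert renal_state.mu_myo == pytest.approx(1.0, abs=1e-3)
        assert raas.PRA == pytest.approx(1.0, abs=1e-3)
        assert anp == pytest.approx(1.0, abs=1e-2)
        assert vp == pytest.approx(1.0, abs=1e-2)


class TestBeatLevel:
    def test_beats_converge_to_periodic_orbit(self, model, baseline_state):
        """Consecutive beats reach <0.1% beat-to-beat change well within
        50 beats from a perturbed start."""
        from cardiorenal import _beat as B
        from cardiorenal.config import build_beat_params
        y = baseline_state.y.copy()
        y[0] += 15.0  # perturb LV volume
        y[3] -= 15.0
        p = build_beat_params(model.cfg)
        summ = np.zeros(B.N_SUM)
        n = B.simulate_burst(y, p, 50, 1e-3, model.cfg.engine.beat_dt, summ)
        assert n < 50

    def test_pv_loop_orientation(self, model, baseline_state):
        """The ventricle does positive work: the loop integral of P dV over
        one steady cycle is positive."""
        tr = model.beat_trace(baseline_state)
        work = -np.trapezoid(tr["P_lv"].to_numpy(), tr["V_lv"].to_numpy())
        assert work > 3000.0  # mmHg·mL, order 0.5 J

    def test_blood_volume_conserved_with_frozen_renal_link(self, model, baseline_state):
        """With excretion frozen to intake the total circulating volume is
        pinned by the venous coupling: drift under 0.01% per simulated hour."""
        from cardiorenal import _beat as B
        from cardiorenal.config import build_beat_params
        y = baseline_state.y.copy()
        p = build_beat_params(model.cfg)
        summ = np.zeros(B.N_SUM)
        B.simulate_burst(y, p, 4200, 0.0, model.cfg.engine.beat_dt, summ)  # ~1 hour
        assert abs(summ[B.S_VTOT] - 4950.0) / 4950.0 < 1e-4

    def test_kernel_matches_library_laws(self, model, baseline_state):
        """The compiled kernel and the pure library functions implement the
        same physics: cross-check pressure, strain and passive stress along
        a recorded beat."""
        cfg = model.cfg
        tr = model.beat_trace(baseline_state)
        w_r = cfg.cardiac.w_r
        for i in range(0, len(tr), 97):
            row = tr.iloc[i]
            lnterm = math.log(1.0 + 120.0 / row.V_lv)
            expected_p = row.sigma_f * 7.50062 * lnterm / 3.0 / (1.0 - 2.0 * w_r * lnterm / 3.0)
            assert row.P_lv == pytest.approx(expected_p, rel=1e-9)
            l_s, _ = sarcomere_kinematics(row.V_lv, 52.0, 120.0, cfg.cardiac.l_s_ref)
            expected_pass = passive_stress(
                l_s, c_p=cfg.cardiac.c_p, k_p=cfg.cardiac.k_p,
                l_s_unloaded=cfg.cardiac.l_s_ref,
            )
            assert row.sigma_pass == pytest.approx(expected_pass, rel=1e-9, abs=1e-12)

    def test_trace_summary_agrees_with_kernel_summary(self, model, baseline_state, baseline_summary):
        tr = model.beat_trace(baseline_state)
        s = extract_beat_summary(tr, hr=70.0)
        assert s.MAP == pytest.approx(baseline_summary.MAP, rel=2e-3)
        assert s.EDV == pytest.approx(baseline_summary.EDV, rel=2e-3)
        assert s.sigma_f_peak == pytest.approx(baseline_summary.sigma_f_peak, rel=2e-3)

    def test_arterial_valves_never_reverse(self, model, baseline_state):
        tr = model.beat_trace(baseline_state)
        # mitral flow may be negative only for a leaky valve; here it is competent
        assert tr["Q_mitral"].min() >= 0.0


class TestOutputs:
    def test_write_and_reread_round_trip(self, model, baseline_state, tmp_path):
        res = model.run_scenario(baseline_state.copy(), InterventionSchedule(), 0.5,
                                 remodeling="none")
        paths = write_outputs(res, tmp_path, config=model.cfg)
        assert paths["summary"].exists() and paths["manifest"].exists()
        back = pd.read_csv(paths["trajectory"])
        orig = res.trajectory.reset_index(drop=True)
        for col in ("MAP", "V_b", "GFR", "sigma_f_peak"):
            assert np.allclose(back[col], orig[col], rtol=1e-9)

    def test_summary_contains_mass_and_ef(self, model, baseline_state, tmp_path):
        import json
        res = model.run_scenario(baseline_state.copy(), InterventionSchedule(), 0.5,
                                 remodeling="none", scenario_name="baseline")
        paths = write_outputs(res, tmp_path)
        data = json.loads(paths["summary"].read_text())
        assert "EF" in data["final_beat"]
        assert "LV_mass" in data
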