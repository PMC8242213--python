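"""Shared fixtures.

The coupled simulations are expensive (a simulated year integrates tens of
thousands of beats), so every long run is a session fixture shared by the
unit, property and acceptance tests that assert on it.
"""

from __future__ import annotations

import pytest

from cardiorenal import (
    CardiorenalModel,
    InterventionEffect,
    InterventionSchedule,
    losartan_effects,
    atenolol_effects,
    make_hypertensive_patient,
)

NA_INTAKE = 100.0 / 1440.0  # mEq/min


@pytest.fixture(scope="session")
def model() -> CardiorenalModel:
    return CardiorenalModel()


@pytest.fixture(scope="session")
def baseline_state(model):
    return model.initialize_steady_state()


@pytest.fixture(scope="session")
def baseline_summary(model, baseline_state):
    return model.beat_summary(baseline_state, max_beats=50)


@pytest.fixture(scope="session")
def baseline_slow_point(model, baseline_summary, baseline_state):
    """Renal + hormonal operating point at the converged baseline."""
    fluids = baseline_state.slow.fluids
    return model.slow_operating_point(
        MAP=baseline_summary.MAP, P_ven=baseline_summary.P_ven_mean,
        EDP=baseline_summary.EDP, c_na=fluids.plasma_na(),
    )


def _stenosis_schedule(mult):
    return InterventionSchedule(
        [InterventionEffect("r_art_mult", mult, ramp_days=365.0, from_value=1.0)]
    )


def _regurg_schedule():
    return InterventionSchedule(
        [InterventionEffect("dp_leak_kpa", 12.5, ramp_days=365.0, from_value=17.5)]
    )


@pytest.fixture(scope="session")
def pressure_overload_fit(model, baseline_state):
    """3x arterial-resistance ramp, one year, both growth laws (fine step)."""
    return model.run_scenario(
        baseline_state.copy(), _stenosis_schedule(3.0), 365.0,
        remodeling="both", macro_step_min=120.0,
    )


@pytest.fixture(scope="session")
def pressure_overload_fit_coarse(model, baseline_state):
    """Same experiment at twice the macro step, for the halving check."""
    return model.run_scenario(
        baseline_state.copy(), _stenosis_schedule(3.0), 365.0,
        remodeling="both", macro_step_min=240.0,
    )


@pytest.fixture(scope="session")
def volume_overload_fit(model, baseline_state):
    """Mitral leak threshold ramp 17.5 -> 12.5 kPa, one year, both laws."""
    return model.run_scenario(
        baseline_state.copy(), _regurg_schedule(), 365.0,
        remodeling="both", macro_step_min=180.0,
    )


@pytest.fixture(scope="session")
def stenosis5_no_remodeling(model, baseline_state):
    return model.run_scenario(
        baseline_state.copy(), _stenosis_schedule(5.0), 365.0,
        remodeling="none", macro_step_min=240.0,
    )


@pytest.fixture(scope="session")
def stenosis5_length_only(model, baseline_state):
    return model.run_scenario(
        baseline_state.copy(), _stenosis_schedule(5.0), 365.0,
        remodeling="length", macro_step_min=240.0,
    )


@pytest.fixture(scope="session")
def stenosis3_diameter_only_long(model, baseline_state):
    """Concentric-only response run past the ramp to its quasi-steady state."""
    return model.run_scenario(
        baseline_state.copy(), _stenosis_schedule(3.0), 950.0,
        remodeling="diameter", macro_step_min=240.0,
    )


@pytest.fixture(scope="session")
def regurg_length_only_long(model, baseline_state):
    """Eccentric-only mitral regurgitation followed long enough to reach
    the self-reinforcing dilation regime."""
    return model.run_scenario(
        baseline_state.copy(), _regurg_schedule(), 1000.0,
        remodeling="length", macro_step_min=240.0,
    )


@pytest.fixture(scope="session")
def baseline_year(model, baseline_state):
    """One simulated year with no intervention and both growth laws on."""
    return model.run_scenario(
        baseline_state.copy(), InterventionSchedule(), 365.0,
        remodeling="both", macro_step_min=360.0,
    )


@pytest.fixture(scope="session")
def renin_inhibition_run(model, baseline_state):
    sch = InterventionSchedule([InterventionEffect("renin_inhib", 0.90)])
    return model.run_scenario(
        baseline_state.copy(), sch, 14.0, remodeling="none", macro_step_min=90.0,
    )


@pytest.fixture(scope="session")
def life_bundle(model):
    """Hypertensive LVH patient plus the four treatment arms."""
    patient, induction = make_hypertensive_patient(model, macro_step_min=240.0)
    from cardiorenal.scenarios import hypertension_effects

    base = hypertension_effects()
    arms = {"induction": induction}
    specs = {
        "losartan": (losartan_effects(), "both"),
        "atenolol": (atenolol_effects(), "both"),
        "renin_only": ([InterventionEffect("renin_inhib", 0.90)], "none"),
        "hr_only": ([InterventionEffect("hr_delta", -8.0)], "none"),
    }
    for name, (effs, mode) in specs.items():
        arms[name] = model.run_scenario(
            patient.copy(), InterventionSchedule(base + effs), 365.0,
            remodeling=mode, macro_step_min=240.0, scenario_name=name,
        )
    return arms
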