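"""Packaged experiments: overload remodeling and antihypertensive therapy.

Each scenario binds an intervention schedule (and, for the treatment
scenarios, a pre-built hypertensive virtual patient) to a duration and a
remodeling mode.  The registry maps scenario names to runner functions
with signature ``runner(model, **overrides) -> SimulationResult``.

Scenario catalogue
------------------
baseline
    No intervention; demonstrates fixed-point persistence.
aortic_stenosis_explore
    Arterial/valvular resistance ramped to 5x over one year — the
    scenario-exploration experiment, usually run under each of the four
    remodeling modes to contrast phenotypes.
aortic_stenosis_fit
    The fitted pressure-overload experiment: 3x resistance ramp, one year,
    both growth laws.
mitral_regurg_explore / mitral_regurg_fit
    Mitral back-leak threshold ramped from 17.5 to 12.5 kPa over one year.
life_losartan / life_atenolol
    One year of therapy on the hypertensive LVH virtual patient
    (losartan: 92% AT1 blockade; atenolol: -8 beats/min and 90%
    renin-secretion inhibition).
fig7_renin_only / fig7_hr_only
    The component effects of atenolol, run at frozen LV geometry so the
    stress responses are not re-normalized by remodeling.
"""

from __future__ import annotations

from typing import Callable

from .engine import (
    CardiorenalModel,
    InterventionEffect,
    InterventionSchedule,
    ModelState,
    SimulationResult,
    atenolol_effects,
    losartan_effects,
)

__all__ = [
    "SCENARIOS",
    "run_scenario_by_name",
    "hypertension_effects",
    "make_hypertensive_patient",
]

#: hypertension induction: preafferent vasoconstriction plus enhanced
#: proximal sodium reabsorption, ramped slowly so hypertrophy tracks the
#: rising load and the patient stays compensated
HYPERTENSION_PREAFF = 2.2
HYPERTENSION_PT = 1.15
HYPERTENSION_RAMP_DAYS = 270.0
HYPERTENSION_DAYS = 900.0


def hypertension_effects() -> list:
    return [
        InterventionEffect("preaff_mult", HYPERTENSION_PREAFF, ramp_days=HYPERTENSION_RAMP_DAYS),
        InterventionEffect("pt_mult", HYPERTENSION_PT, ramp_days=HYPERTENSION_RAMP_DAYS),
    ]


def aortic_stenosis_effects(multiplier: float, ramp_days: float = 365.0) -> list:
    return [InterventionEffect("r_art_mult", multiplier, ramp_days=ramp_days, from_value=1.0)]


def mitral_regurg_effects(
    threshold_from_kpa: float = 17.5, threshold_to_kpa: float = 12.5, ramp_days: float = 365.0
) -> list:
    return [InterventionEffect("dp_leak_kpa", threshold_to_kpa, ramp_days=ramp_days,
                               from_value=threshold_from_kpa)]


def make_hypertensive_patient(
    model: CardiorenalModel,
    macro_step_min: float | None = None,
) -> tuple[ModelState, SimulationResult]:
    """Induce hypertension and run remodeling to a quasi-steady LVH state.

    Returns the patient state (still under the induction schedule) and the
    induction trajectory.  The induction is held during any subsequent
    treatment run.
    """
    state = model.initialize_steady_state()
    res = model.run_scenario(
        state, InterventionSchedule(hypertension_effects()), HYPERTENSION_DAYS,
        remodeling="both", macro_step_min=macro_step_min or 240.0,
        scenario_name="hypertension_induction",
    )
    if not res.completed:
        raise RuntimeError("hypertension induction broke down")
    return res.final_state, res


def _overload_runner(effects_builder: Callable[[], list], default_mode: str):
    def run(model: CardiorenalModel, duration_days: float = 365.0,
            remodeling: str | None = None, macro_step_min: float | None = None,
            scenario_name: str = "") -> SimulationResult:
        state = model.initialize_steady_state()
        return model.run_scenario(
            state, InterventionSchedule(effects_builder()), duration_days,
            remodeling=remodeling or default_mode, macro_step_min=macro_step_min,
            scenario_name=scenario_name,
        )
    return run


def _treatment_runner(treatment_effects: Callable[[], list], remodeling: str):
    def run(model: CardiorenalModel, duration_days: float = 365.0,
            macro_step_min: float | None = None, patient: ModelState | None = None,
            scenario_name: str = "", **_ignored) -> SimulationResult:
        if patient is None:
            patient, _ = make_hypertensive_patient(model, macro_step_min=macro_step_min)
        schedule = InterventionSchedule(hypertension_effects() + treatment_effects())
        return model.run_scenario(
            patient.copy(), schedule, duration_days, remodeling=remodeling,
            macro_step_min=macro_step_min, scenario_name=scenario_name,
        )
    return run


def _baseline_runner(model: CardiorenalModel, duration_days: float = 365.0,
                     remodeling: str = "both", macro_step_min: float | None = None,
                     scenario_name: str = "baseline") -> SimulationResult:
    state = model.initialize_steady_state()
    return model.run_scenario(state, InterventionSchedule(), duration_days,
                              remodeling=remodeling, macro_step_min=macro_step_min,
                              scenario_name=scenario_name)


SCENARIOS: dict[str, Callable] = {
    "baseline": _baseline_runner,
    "aortic_stenosis_explore": _overload_runner(lambda: aortic_stenosis_effects(5.0), "both"),
    "aortic_stenosis_fit": _overload_runner(lambda: aortic_stenosis_effects(3.0), "both"),
    "mitral_regurg_explore": _overload_runner(mitral_regurg_effects, "both"),
    "mitral_regurg_fit": _overload_runner(mitral_regurg_effects, "both"),
    "life_losartan": _treatment_runner(losartan_effects, "both"),
    "life_atenolol": _treatment_runner(atenolol_effects, "both"),
    # component decomposition at frozen LV geometry
    "fig7_renin_only": _treatment_runner(
        lambda: [InterventionEffect("renin_inhib", 0.90)], "none"),
    "fig7_hr_only": _treatment_runner(
        lambda: [InterventionEffect("hr_delta", -8.0)], "none"),
}


def run_scenario_by_name(model: CardiorenalModel, name: str, **kwargs) -> SimulationResult:
    """Look up and run a packaged scenario; unknown names raise KeyError."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kwargs.setdefault("scenario_name", name)
    return SCENARIOS[name](model, **kwargs)
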