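"""Multi-rate simulation engine.

Three timescales are bound together:

* beats (~1 s): the compiled kernel integrates the ventricles and
  circulation to beat-to-beat periodicity in short bursts;
* homeostasis (hours-days): per-beat summaries (MAP, venous pressure, EDP,
  CO) are held constant over a macro-step while the renal/hormonal algebra
  and the whole-body Na/water balances advance;
* remodeling (months): myocyte diameter/length increments integrate the
  per-beat stress summaries at rates of μm/year.

The kidney and the circulation exchange two quantities: MAP (and venous
pressure) flow from the beat summary into the renal operating point, and
the renal blood volume flows back as the target total circulating volume,
enforced through the venous compartment with rate ``k_ven_target``.  The
venous volume relaxes toward ``V_ven_target = V_b - sum(other
compartments)``; the stabilizing sign (target minus current) is used, which
is the only sign that lets the volume "adjust and reach this target".

Hormones (RAAS, ANP, vasopressin) are held at their quasi-steady values at
each macro-step: their half-lives (minutes) are far below the macro-step,
so the explicit first-order kinetics in :mod:`cardiorenal.neurohormonal`
would only resolve transients the slow loop cannot see.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from . import _beat as B
from .cardiac import BeatSummary
from .config import ModelConfig, build_beat_params
from .neurohormonal import (
    RAASState,
    aldosterone_mr,
    anp_signal,
    bounded_effect,
    raas_steady_state,
    vasopressin_signal,
)
from .remodeling import (
    MyocyteGeometry,
    diameter_growth_rate,
    length_growth_rate,
    lv_mass,
    h_over_r,
    unloaded_cavity_volume,
    wall_composition,
)
from .renal import (
    BodyFluidState,
    RenalBaseline,
    RenalState,
    fluid_balance,
    renal_operating_point,
)
from .units import KPA_PER_MMHG, MIN_PER_DAY, MIN_PER_YEAR

__all__ = [
    "InterventionEffect",
    "InterventionSchedule",
    "ModelState",
    "SimulationResult",
    "CardiorenalModel",
    "venous_coupling",
    "apply_intervention",
    "losartan_effects",
    "atenolol_effects",
]

_EFFECT_KINDS = {
    "r_art_mult", "dp_leak_kpa", "at1_block", "hr_delta", "renin_inhib",
    "na_intake_mult", "water_intake_mult", "preaff_mult", "pt_mult",
    "co_setpoint_mult",
}


def venous_coupling(V_ven: float, V_ven_target: float, Q_in: float, Q_out: float, k: float) -> float:
    """dV_ven/dt with the renal volume link (stabilizing form).

    ``Q`` in L/min, volumes in mL, ``k`` in 1/min -> returns mL/min.
    """
    if k <= 0:
        raise ValueError("coupling rate must be positive")
    return (Q_in - Q_out) * 1000.0 + k * (V_ven_target - V_ven)


@dataclass
class InterventionEffect:
    """One timed effect: linear ramp of a named model input.

    ``from_value`` of None means "the scenario baseline" (1 for multipliers,
    0 for deltas/fractions, the configured leak threshold for the mitral
    valve).
    """

    kind: str
    to_value: float
    start_day: float = 0.0
    ramp_days: float = 0.0
    from_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _EFFECT_KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.ramp_days < 0:
            raise ValueError("ramp duration cannot be negative")

    def default_from(self) -> float:
        if self.kind.endswith("_mult"):
            return 1.0
        return 0.0

    def value(self, t_day: float) -> float:
        start = self.from_value if self.from_value is not None else self.default_from()
        if t_day <= self.start_day:
            return start
        if self.ramp_days == 0.0 or t_day >= self.start_day + self.ramp_days:
            return self.to_value
        frac = (t_day - self.start_day) / self.ramp_days
        return start + frac * (self.to_value - start)


@dataclass
class InterventionSchedule:
    effects: list = field(default_factory=list)

    def value(self, kind: str, t_day: float, default: float) -> float:
        out = default
        for e in self.effects:
            if e.kind == kind:
                v = e.value(t_day)
                if kind.endswith("_mult"):
                    out *= v
                elif kind == "hr_delta":
                    out += v
                else:
                    out = v
        return out

    def has(self, kind: str) -> bool:
        return any(e.kind == kind for e in self.effects)


def apply_intervention(schedule: InterventionSchedule, effect: InterventionEffect) -> InterventionSchedule:
    """Return a new schedule with the effect appended (no-op magnitudes allowed)."""
    return InterventionSchedule(effects=[*schedule.effects, effect])


def losartan_effects(start_day: float = 0.0, block: float = 0.92) -> list:
    """Losartan 100 mg: sustained AT1-receptor blockade."""
    return [InterventionEffect("at1_block", block, start_day=start_day)]


def atenolol_effects(
    start_day: float = 0.0, hr_drop: float = 8.0, renin_inhibition: float = 0.90
) -> list:
    """Atenolol: heart-rate reduction plus renin-secretion inhibition.

    The 90% secretion inhibition produces roughly a 40% drop in renin
    activity once the closed-loop feedback re-opens.
    """
    return [
        InterventionEffect("hr_delta", -hr_drop, start_day=start_day),
        InterventionEffect("renin_inhib", renin_inhibition, start_day=start_day),
    ]


@dataclass
class SlowState:
    fluids: BodyFluidState
    mu_wba: float = 1.0
    dD: float = 0.0
    dL: float = 0.0
    at1_cache: float = 1.0
    na_balance: float = 0.0      # cumulative intake - excretion (mEq)
    water_balance: float = 0.0   # cumulative intake - urine (L)


@dataclass
class ModelState:
    y: np.ndarray
    slow: SlowState
    t_min: float = 0.0

    def copy(self) -> "ModelState":
        return ModelState(
            y=self.y.copy(),
            slow=replace(self.slow, fluids=replace(self.slow.fluids)),
            t_min=self.t_min,
        )


@dataclass
class SimulationResult:
    trajectory: pd.DataFrame
    final_summary: BeatSummary
    final_state: ModelState
    status: str  # "completed" | "breakdown"
    scenario: str = ""

    @property
    def completed(self) -> bool:
        return self.status == "completed"


def _summary_from_array(s: np.ndarray) -> BeatSummary:
    return BeatSummary(
        SBP=s[B.S_SBP], DBP=s[B.S_DBP], MAP=s[B.S_MAP], EDP=s[B.S_EDP],
        PSP=s[B.S_PSP], EDV=s[B.S_EDV], ESV=s[B.S_ESV], SV=s[B.S_SV],
        EF=s[B.S_EF], CO=s[B.S_CO],
        sigma_f_peak=s[B.S_SIGPEAK] * KPA_PER_MMHG,
        sigma_f_ED=s[B.S_SIGED] * KPA_PER_MMHG,
        HR=s[B.S_HR], P_ven_mean=s[B.S_PVEN], P_pa_mean=s[B.S_PPA],
        P_pv_mean=s[B.S_PPV], regurgitant_volume=s[B.S_REGURG],
        n_beats=int(s[B.S_NBEATS]),
    )


class CardiorenalModel:
    """The coupled model bound to one configuration."""

    def __init__(self, config: ModelConfig | None = None):
        self.cfg = config or ModelConfig()
        self.renal_params = self.cfg.renal.to_params()
        self.renal_base = RenalBaseline.from_params(self.renal_params)
        self.raas_params = self.cfg.neurohormonal.raas_params()
        self.sig_params = self.cfg.neurohormonal.signal_params()
        self.remodel_params = self.cfg.remodeling_params()
        self.D_myo0 = self.cfg.remodeling.derived_D_myo0()

    # ------------------------------------------------------------------ geometry
    def lv_geometry(self, dD: float, dL: float) -> tuple[float, float]:
        """(V_w, V_cav0) of the LV for given remodeling increments."""
        r = self.cfg.remodeling
        geom = MyocyteGeometry(N_myo=r.N_myo, D_myo0=self.D_myo0, L_myo0=r.L_myo0, dD=dD, dL=dL)
        v_w = wall_composition(geom, r.V_IS, r.V_f).V_w
        v_cav0 = unloaded_cavity_volume(r.V_LV0, dL, r.L_myo0)
        return v_w, v_cav0

    # ------------------------------------------------------------- operating point
    def slow_operating_point(
        self,
        MAP: float,
        P_ven: float,
        EDP: float,
        c_na: float,
        at1_block: float = 0.0,
        renin_inhib: float = 0.0,
        preaff_mult: float = 1.0,
        pt_mult: float = 1.0,
        at1_warm: float = 1.0,
    ) -> tuple[RenalState, RAASState, float, float]:
        """Quasi-steady renal + hormonal state at frozen hemodynamics.

        Outer damped iteration between the renal network (which needs
        AT1-bound AngII and aldosterone) and the RAAS fixed point (which
        needs macula densa flow).  Returns (renal, raas, ANP, vasopressin).
        """
        anp = anp_signal(EDP / self.cfg.setpoints.EDP0, self.sig_params)
        vp = vasopressin_signal(c_na / self.renal_params.c_na0, self.sig_params)
        at1 = at1_warm
        renal_state = None
        raas = None
        for _ in range(20):
            ald, mr = aldosterone_mr(at1, self.raas_params)
            renal_state = renal_operating_point(
                MAP, P_ven, c_na, self.renal_params, self.renal_base,
                at1=at1, mr=mr, anp=anp, vasopressin=vp,
                preaff_mult=preaff_mult, pt_mult=pt_mult, sig_params=self.sig_params,
            )
            raas = raas_steady_state(
                renal_state.nephron.phi_md / self.renal_base.phi_md0,
                at1_block_fraction=at1_block, inhibition_fraction=renin_inhib,
                params=self.raas_params,
            )
            if abs(raas.AT1_AngII - at1) < 1e-10:
                at1 = raas.AT1_AngII
                break
            at1 += 0.6 * (raas.AT1_AngII - at1)
        return renal_state, raas, anp, vp

    # ------------------------------------------------------------------- stepping
    def _beat_params(self, state: ModelState, schedule: InterventionSchedule, t_day: float):
        cfg = self.cfg
        hr = schedule.value("hr_delta", t_day, cfg.cardiac.hr)
        r_art_mult = schedule.value("r_art_mult", t_day, 1.0)
        dp_leak = cfg.circulation.dP_leak
        if schedule.has("dp_leak_kpa"):
            dp_leak = schedule.value("dp_leak_kpa", t_day, 0.0)
        v_w, v_cav0 = self.lv_geometry(state.slow.dD, state.slow.dL)
        r_per_mult = state.slow.mu_wba * bounded_effect(
            state.slow.at1_cache, cfg.neurohormonal.g_at1_sys, cfg.neurohormonal.s_at1_sys
        )
        vb = state.slow.fluids.blood_volume(self.renal_params, self.renal_base)
        p = build_beat_params(
            cfg, hr=hr, vb_target_ml=vb * 1000.0, r_art_mult=r_art_mult,
            dp_leak_kpa=dp_leak, r_per_mult=r_per_mult, v_w_lv=v_w, v_cav0_lv=v_cav0,
        )
        return p, hr, r_art_mult, dp_leak, v_w

    def step(
        self,
        state: ModelState,
        schedule: InterventionSchedule,
        dt_min: float,
        kd_mult: float = 1.0,
        kl_mult: float = 1.0,
        max_beats: int | None = None,
    ) -> dict:
        """Advance one macro-step; mutates ``state`` and returns a record."""
        cfg = self.cfg
        t_day = state.t_min / MIN_PER_DAY
        p, hr, r_art_mult, dp_leak, v_w = self._beat_params(state, schedule, t_day)

        summ = np.zeros(B.N_SUM)
        n = B.simulate_burst(
            state.y, p,
            max_beats if max_beats is not None else cfg.engine.burst_max_beats,
            cfg.engine.burst_tol, cfg.engine.beat_dt, summ,
        )
        if not np.all(np.isfinite(state.y)) or summ[B.S_EF] <= 0.02 or state.y[0] <= 0:
            raise FloatingPointError("circulation breakdown (EF collapse or invalid state)")

        fluids = state.slow.fluids
        c_na = fluids.plasma_na()
        renal_state, raas, anp, vp = self.slow_operating_point(
            MAP=summ[B.S_MAP], P_ven=summ[B.S_PVEN], EDP=summ[B.S_EDP], c_na=c_na,
            at1_block=schedule.value("at1_block", t_day, 0.0),
            renin_inhib=schedule.value("renin_inhib", t_day, 0.0),
            preaff_mult=schedule.value("preaff_mult", t_day, 1.0),
            pt_mult=schedule.value("pt_mult", t_day, 1.0),
            at1_warm=state.slow.at1_cache,
        )
        state.slow.at1_cache = raas.AT1_AngII

        na_in = self.renal_params.na_intake0 * schedule.value("na_intake_mult", t_day, 1.0)
        w_in = self.renal_params.water_intake0 * schedule.value("water_intake_mult", t_day, 1.0)
        na_out = renal_state.nephron.na_excretion
        urine = renal_state.nephron.urine_flow

        sig_peak = summ[B.S_SIGPEAK] * KPA_PER_MMHG
        sig_ed = summ[B.S_SIGED] * KPA_PER_MMHG
        rp = self.remodel_params
        dd_floor = cfg.remodeling.dD_floor_frac * self.D_myo0

        n_sub = cfg.engine.slow_substeps
        dt_sub = dt_min / n_sub
        for _ in range(n_sub):
            fluids, _ = fluid_balance(
                fluids, na_in, na_out, w_in, urine, dt_sub, self.renal_params, self.renal_base
            )
            if kd_mult > 0.0:
                rate_d = kd_mult * diameter_growth_rate(sig_peak, rp, state.slow.dD)
                state.slow.dD = min(max(state.slow.dD + rate_d * dt_sub / MIN_PER_YEAR, dd_floor), rp.dD_max)
            if kl_mult > 0.0:
                rate_l = kl_mult * length_growth_rate(sig_ed, rp, state.slow.dL)
                state.slow.dL = min(state.slow.dL + rate_l * dt_sub / MIN_PER_YEAR, rp.dL_max)
        state.slow.fluids = fluids
        state.slow.na_balance += (na_in - na_out) * dt_min
        state.slow.water_balance += (w_in - urine) * dt_min / 1000.0

        co_set = cfg.setpoints.CO0 * schedule.value("co_setpoint_mult", t_day, 1.0)
        mu_target = (summ[B.S_CO] / co_set) ** cfg.neurohormonal.p_wba
        mu_target = min(max(mu_target, cfg.neurohormonal.wba_min), cfg.neurohormonal.wba_max)
        relax = 1.0 - math.exp(-dt_min / cfg.neurohormonal.tau_wba)
        state.slow.mu_wba += (mu_target - state.slow.mu_wba) * relax

        state.t_min += dt_min

        vb = fluids.blood_volume(self.renal_params, self.renal_base)
        v_cav0 = self.lv_geometry(state.slow.dD, state.slow.dL)[1]
        return {
            "time_day": state.t_min / MIN_PER_DAY,
            "MAP": summ[B.S_MAP], "SBP": summ[B.S_SBP], "DBP": summ[B.S_DBP],
            "PSP": summ[B.S_PSP], "EDP": summ[B.S_EDP],
            "EDV": summ[B.S_EDV], "ESV": summ[B.S_ESV], "SV": summ[B.S_SV],
            "EF": summ[B.S_EF], "CO": summ[B.S_CO], "HR": hr,
            "P_ven": summ[B.S_PVEN], "P_pulm_art": summ[B.S_PPA], "P_pulm_ven": summ[B.S_PPV],
            "sigma_f_peak": sig_peak, "sigma_f_ED": sig_ed,
            "V_b": vb, "ECF": fluids.V_ecf,
            "ISF": fluids.interstitial_volume(self.renal_params, self.renal_base),
            "plasma_na": fluids.plasma_na(),
            "Na_excretion": na_out, "urine_flow": urine,
            "Na_balance": state.slow.na_balance, "water_balance": state.slow.water_balance,
            "GFR": renal_state.nephron.GFR, "RBF": renal_state.vasc.RBF * 1000.0,
            "P_gc": renal_state.vasc.P_gc, "RIHP": renal_state.vasc.RIHP,
            "PRC": raas.PRC, "PRA": raas.PRA, "AngII": raas.AngII,
            "AT1_AngII": raas.AT1_AngII, "aldosterone": raas.aldosterone,
            "ANP": anp, "vasopressin": vp,
            "TGF": renal_state.mu_tgf, "myogenic": renal_state.mu_myo,
            "PN_signal": renal_state.rihp_norm, "WBA": state.slow.mu_wba,
            "dD": state.slow.dD, "dL": state.slow.dL,
            "V_w": v_w, "V_cav0": v_cav0, "LV_mass": lv_mass(v_w, cfg.remodeling.density),
            "h_over_R": h_over_r(summ[B.S_EDV], v_w),
            "regurg_ml": summ[B.S_REGURG],
            "r_art_mult": r_art_mult,
            "dP_leak": dp_leak if dp_leak is not None else float("nan"),
            "n_beats": n,
        }

    # -------------------------------------------------------------- initialization
    def initialize_steady_state(self, settle_days: float | None = None) -> ModelState:
        """Build the baseline state and run it to the coupled steady state.

        Remodeling is frozen during initialization.  Verifies that the
        regulatory signals sit at their setpoints and the hypertrophic
        signals are (one-sided) zero; raises if the state keeps drifting.
        """
        cfg = self.cfg
        ci = cfg.circulation
        vb_ml = cfg.renal.V_b0 * 1000.0
        y = np.zeros(11)
        y[0] = 103.0
        y[1] = ci.V0_art + 80.0 * ci.C_art
        y[2] = ci.V0_per + 70.0 * ci.C_per
        y[4] = 100.0
        y[5] = ci.V0_pulm_art + 12.0 * ci.C_pulm_art
        y[6] = ci.V0_pulm_ven + 9.0 * ci.C_pulm_ven
        y[3] = vb_ml - (y[0] + y[1] + y[2] + y[4] + y[5] + y[6])
        y[7] = 80.0
        y[8] = 80.0

        slow = SlowState(
            fluids=BodyFluidState(body_na=self.renal_base.body_na0, V_ecf=self.renal_base.V_ecf0)
        )
        state = ModelState(y=y, slow=slow)

        p = build_beat_params(cfg)
        summ = np.zeros(B.N_SUM)
        B.simulate_burst(state.y, p, cfg.engine.init_max_beats, cfg.engine.init_tol,
                         cfg.engine.beat_dt, summ)

        # coupled settling with remodeling frozen
        days = cfg.engine.settle_days if settle_days is None else settle_days
        schedule = InterventionSchedule()
        n_steps = max(int(round(days * MIN_PER_DAY / cfg.engine.macro_step_min)), 1)
        first = last = None
        for i in range(n_steps):
            rec = self.step(state, schedule, cfg.engine.macro_step_min, kd_mult=0.0, kl_mult=0.0)
            if i == n_steps // 2:
                first = rec
            last = rec
        if first is not None and days > 0:
            span_day = (last["time_day"] - first["time_day"]) or 1.0
            worst, worst_key = 0.0, ""
            for key in ("MAP", "EDV", "V_b", "Na_excretion"):
                drift = abs(last[key] - first[key]) / max(abs(last[key]), 1e-9) / span_day
                if drift > worst:
                    worst, worst_key = drift, key
            if worst > cfg.engine.steady_drift_tol:
                raise RuntimeError(
                    f"steady-state initialization did not converge: {worst_key} "
                    f"drifts {worst:.2%}/day (tolerance {cfg.engine.steady_drift_tol:.2%})"
                )
        state.t_min = 0.0
        state.slow.na_balance = 0.0
        state.slow.water_balance = 0.0
        return state

    def beat_summary(self, state: ModelState, schedule: InterventionSchedule | None = None,
                     max_beats: int | None = None) -> BeatSummary:
        """Run a burst (without advancing slow time) and summarize the last beat."""
        schedule = schedule or InterventionSchedule()
        t_day = state.t_min / MIN_PER_DAY
        p, *_ = self._beat_params(state, schedule, t_day)
        summ = np.zeros(B.N_SUM)
        y = state.y.copy()
        B.simulate_burst(y, p, max_beats or self.cfg.engine.burst_max_beats,
                         self.cfg.engine.burst_tol, self.cfg.engine.beat_dt, summ)
        return _summary_from_array(summ)

    def beat_trace(self, state: ModelState, schedule: InterventionSchedule | None = None,
                   n_samples: int = 860) -> pd.DataFrame:
        """Record one steady beat as a DataFrame (columns per TRACE_COLS)."""
        schedule = schedule or InterventionSchedule()
        p, *_ = self._beat_params(state, schedule, state.t_min / MIN_PER_DAY)
        y = state.y.copy()
        summ = np.zeros(B.N_SUM)
        B.simulate_burst(y, p, self.cfg.engine.burst_max_beats, self.cfg.engine.burst_tol,
                         self.cfg.engine.beat_dt, summ)
        out = np.zeros((n_samples + 1, len(B.TRACE_COLS)))
        B.simulate_trace(y, p, self.cfg.engine.beat_dt, out)
        df = pd.DataFrame(out, columns=list(B.TRACE_COLS))
        df["sigma_f"] *= KPA_PER_MMHG
        df["sigma_act"] *= KPA_PER_MMHG
        df["sigma_pass"] *= KPA_PER_MMHG
        return df

    # ------------------------------------------------------------------ scenarios
    def run_scenario(
        self,
        state: ModelState,
        schedule: InterventionSchedule,
        duration_days: float,
        remodeling: str = "both",
        macro_step_min: float | None = None,
        record_every: int = 1,
        scenario_name: str = "",
    ) -> SimulationResult:
        """Advance the multi-rate loop for ``duration_days``.

        ``remodeling`` selects which growth laws are active
        (both/diameter/length/none).  A physiological breakdown (EF
        collapse, negative volumes, renal perfusion failure) terminates the
        run with status ``"breakdown"`` — a valid, reportable endpoint.
        """
        kd_mult, kl_mult = {
            "both": (1.0, 1.0), "diameter": (1.0, 0.0),
            "length": (0.0, 1.0), "none": (0.0, 0.0),
        }[remodeling]
        dt = macro_step_min or self.cfg.engine.macro_step_min
        n_steps = int(round(duration_days * MIN_PER_DAY / dt))
        records = []
        status = "completed"
        last_summary = None
        for i in range(n_steps):
            try:
                rec = self.step(state, schedule, dt, kd_mult=kd_mult, kl_mult=kl_mult)
            except (FloatingPointError, ValueError, RuntimeError):
                status = "breakdown"
                break
            if i % record_every == 0 or i == n_steps - 1:
                records.append(rec)
            last_summary = rec
        traj = pd.DataFrame(records)
        if last_summary is None:
            raise RuntimeError("scenario broke down before completing a single macro-step")
        final = self.beat_summary(state, schedule) if status == "completed" else BeatSummary(
            SBP=last_summary["SBP"], DBP=last_summary["DBP"], MAP=last_summary["MAP"],
            EDP=last_summary["EDP"], PSP=last_summary["PSP"], EDV=last_summary["EDV"],
            ESV=last_summary["ESV"], SV=last_summary["SV"], EF=last_summary["EF"],
            CO=last_summary["CO"], sigma_f_peak=last_summary["sigma_f_peak"],
            sigma_f_ED=last_summary["sigma_f_ED"], HR=last_summary["HR"],
        )
        return SimulationResult(
            trajectory=traj, final_summary=final, final_state=state,
            status=status, scenario=scenario_name,
        )
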