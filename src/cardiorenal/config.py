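"""Model configuration: the single source of truth for all parameters.

Every parameter carries a unit and a provenance tag (``table1`` for values
taken from the published cardiac parameter table, ``calibrated`` for values
fitted so the baseline reproduces the published operating point,
``assumed`` for standard physiological constants).  Configs load from YAML
or JSON, reject unknown keys, and round-trip exactly through
``dump_config``/``load_config``.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any, Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import _beat as B
from .neurohormonal import RAASParams, SignalParams
from .remodeling import RemodelingParams
from .renal import RenalParams
from .units import MMHG_PER_KPA, R_CLINICAL_TO_BEAT


def P(default, unit: str, provenance: str, description: str = "", **kw):
    return Field(default, json_schema_extra={
        "unit": unit, "provenance": provenance, "description": description}, **kw)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CardiacConfig(_Section):
    hr: float = P(70.0, "beats/min", "table1", "resting heart rate", gt=0)
    l_s_ref: float = P(2.0, "um", "assumed", "sarcomere length at unloaded cavity volume")
    l_s_zero: float = P(1.55, "um", "assumed", "zero active force sarcomere length")
    l_s_sat: float = P(2.326616, "um", "calibrated", "length at which active force saturates")
    v_max: float = P(15.006913, "um/s", "calibrated", "unloaded shortening velocity")
    f_vel_max: float = P(1.4, "dimensionless", "assumed", "lengthening force cap")
    sigma_act_max: float = P(58.0, "kPa", "calibrated",
                             "maximal active fiber tension (contractile ceiling)", gt=0)
    sigma_act_knee: float = P(50.0, "kPa", "calibrated",
                              "active tension above which the reserve saturates", gt=0)
    tau_vel: float = P(0.01, "s", "assumed", "sarcomere velocity filter time constant")
    t_sys_ref: float = P(0.30854678463318497, "s", "calibrated", "twitch duration at reference cycle length", gt=0)
    t_peak_frac: float = P(0.929919, "fraction", "calibrated", "twitch peak position within systole", gt=0.05, lt=0.95)
    cycle_ref: float = P(60.0 / 70.0, "s", "assumed", "reference cycle length for twitch scaling")
    sigma_a0_lv: float = P(102.43752950453923, "kPa", "calibrated", "LV isometric active stress scale", gt=0)
    sigma_a0_rv: float = P(68.168259, "kPa", "calibrated", "RV isometric active stress scale", gt=0)
    c_p: float = P(0.22256259614195875, "kPa", "calibrated", "passive stress scale (both ventricles)", gt=0)
    k_p: float = P(9.412039, "1/um", "calibrated", "passive stress exponent", gt=0)
    w_r: float = P(0.045, "dimensionless", "calibrated", "radial matrix stress weight (sigma_mr = -w_r*P)")
    V_w_rv: float = P(40.0, "mL", "assumed", "RV wall volume", gt=0)
    V_cav0_rv: float = P(70.0, "mL", "calibrated", "RV unloaded cavity volume", gt=0)


class CirculationConfig(_Section):
    # resistances, mmHg·min/L (clinical convention)
    R_art: float = P(0.949796, "mmHg·min/L", "calibrated", "aortic valve + large artery resistance", gt=0)
    R_mitral: float = P(0.18, "mmHg·min/L", "calibrated", "mitral path resistance", gt=0)
    R_tricuspid: float = P(0.15, "mmHg·min/L", "assumed", gt=0)
    R_pulm_valve: float = P(0.12, "mmHg·min/L", "assumed", gt=0)
    R_art_per: float = P(2.0, "mmHg·min/L", "calibrated", "arterial-to-peripheral bed resistance", gt=0)
    R_per: float = P(13.85, "mmHg·min/L", "calibrated", "peripheral bed outflow resistance", gt=0)
    R_pulm: float = P(0.8733081468315215, "mmHg·min/L", "calibrated", "pulmonary arterial outflow resistance", gt=0)
    I_art: float = P(0.0014, "mmHg·min²/L", "assumed", "systemic arterial inertance", ge=0)
    I_pulm: float = P(0.0007, "mmHg·min²/L", "assumed", "pulmonary arterial inertance", ge=0)
    # capacitances, mL/mmHg
    C_art: float = P(0.986537, "mL/mmHg", "calibrated", gt=0)
    C_per: float = P(3.0, "mL/mmHg", "calibrated", gt=0)
    C_ven: float = P(110.0, "mL/mmHg", "calibrated", gt=0)
    C_pulm_art: float = P(4.0, "mL/mmHg", "calibrated", gt=0)
    C_pulm_ven: float = P(12.0, "mL/mmHg", "calibrated", gt=0)
    # equilibrium volumes, mL
    V0_art: float = P(294.0, "mL", "calibrated")
    V0_per: float = P(125.0, "mL", "calibrated")
    V0_ven: float = P(3237.032329734049, "mL", "calibrated")
    V0_pulm_art: float = P(59.0, "mL", "calibrated")
    V0_pulm_ven: float = P(387.0, "mL", "calibrated")
    dP_leak: float | None = P(None, "kPa", "assumed", "mitral leak threshold; None = competent valve")
    valve_smoothing: float = P(0.0, "mmHg", "assumed", "diode smoothing width (0 = hard switching)")


class RemodelingConfig(_Section):
    K_d0: float = P(43.8, "um/year", "table1", "diameter growth rate constant", ge=0)
    K_l0: float = P(17.5, "um/year", "table1", "length growth rate constant", ge=0)
    sigma_peak0: float = P(49.2, "kPa", "table1", "peak systolic stress setpoint", gt=0)
    sigma_ED0: float = P(4.5, "kPa", "table1", "end-diastolic stress setpoint", gt=0)
    dD_max: float = P(25.0, "um", "table1", "maximum diameter increase", gt=0)
    dL_max: float = P(115.0, "um", "table1", "maximum length increase", gt=0)
    dD_floor_frac: float = P(-0.5, "dimensionless", "assumed", "diameter regression floor, fraction of D_myo0")
    N_myo: float = P(3.3e9, "count", "table1", gt=0)
    L_myo0: float = P(115.0, "um", "table1", gt=0)
    D_myo0: float | None = P(None, "um", "calibrated",
                             "baseline myocyte diameter; None derives it from V_w0, N_myo, L_myo0")
    V_IS: float = P(26.4, "mL", "table1", "interstitial volume", ge=0)
    V_f: float = P(4.8, "mL", "table1", "fibrosis volume", ge=0)
    V_LV0: float = P(52.0, "mL", "table1", "unpressurized LV cavity volume", gt=0)
    V_w0: float = P(120.0, "mL", "table1", "baseline LV wall volume", gt=0)
    density: float = P(1.05, "g/mL", "assumed", "myocardial density", gt=0)
    bsa: float = P(1.8, "m²", "assumed", "body surface area for LVMI", gt=0)

    def derived_D_myo0(self) -> float:
        if self.D_myo0 is not None:
            return self.D_myo0
        v_myo0 = (self.V_w0 - self.V_IS - self.V_f) * 1e12  # um^3
        return math.sqrt(4.0 * v_myo0 / (math.pi * self.N_myo * self.L_myo0))


class RenalConfig(_Section):
    MAP0: float = P(81.3196, "mmHg", "calibrated", "baseline mean arterial pressure")
    P_ven0: float = P(2.1007, "mmHg", "calibrated", "baseline mean venous pressure")
    RBF0: float = P(1.0, "L/min", "table2-equivalent", "baseline renal blood flow")
    GFR0: float = P(100.0, "mL/min", "table2-equivalent")
    P_bowman: float = P(18.0, "mmHg", "assumed")
    pi_gc: float = P(28.0, "mmHg", "assumed", "glomerular oncotic pressure")
    R_preaff0: float = P(14.0, "mmHg·min/L", "assumed")
    R_aff0: float = P(11.0, "mmHg·min/L", "assumed")
    R_eff0: float = P(44.0, "mmHg·min/L", "assumed")
    f_pt0: float = P(0.70, "fraction", "assumed", "proximal Na reabsorption fraction", gt=0, lt=1)
    f_ld0: float = P(0.80, "fraction", "assumed", "loop+distal Na reabsorption fraction", gt=0, lt=1)
    f_ldw0: float = P(0.80, "fraction", "assumed", "loop+distal water reabsorption fraction", gt=0, lt=1)
    na_intake0: float = P(100.0 / 1440.0, "mEq/min", "assumed", "dietary sodium intake")
    water_intake0: float = P(1.0, "mL/min", "assumed")
    c_na0: float = P(140.0, "mEq/L", "assumed", "baseline plasma Na")
    urine_min: float = P(0.05, "mL/min", "assumed", "obligate urine flow")
    RIHP0: float = P(4.0, "mmHg", "assumed", "baseline renal interstitial hydrostatic pressure")
    rihp_p_gain: float = P(4.0, "dimensionless", "calibrated")
    rihp_q_gain: float = P(0.5, "dimensionless", "calibrated")
    g_pn_pt: float = P(0.18, "dimensionless", "calibrated")
    s_pn_pt: float = P(2.0, "dimensionless", "calibrated")
    g_pn_cd: float = P(0.09, "dimensionless", "calibrated")
    s_pn_cd: float = P(3.0, "dimensionless", "calibrated")
    g_at1_pt: float = P(0.08, "dimensionless", "calibrated")
    s_at1_pt: float = P(1.5, "dimensionless", "calibrated")
    g_mr_cd: float = P(0.02, "dimensionless", "calibrated")
    s_mr_cd: float = P(2.0, "dimensionless", "calibrated")
    g_anp_cd: float = P(0.02, "dimensionless", "calibrated")
    s_anp_cd: float = P(1.0, "dimensionless", "calibrated")
    g_vp_cdw: float = P(0.12, "dimensionless", "calibrated")
    s_vp_cdw: float = P(2.0, "dimensionless", "calibrated")
    g_at1_eff: float = P(0.35, "dimensionless", "calibrated")
    s_at1_eff: float = P(1.5, "dimensionless", "calibrated")
    g_at1_pre: float = P(0.15, "dimensionless", "calibrated")
    s_at1_pre: float = P(1.5, "dimensionless", "calibrated")
    g_at1_aff: float = P(0.10, "dimensionless", "calibrated")
    s_at1_aff: float = P(1.5, "dimensionless", "calibrated")
    V_b0: float = P(4.95, "L", "table2-equivalent", "baseline blood volume")
    V_isf0: float = P(12.0, "L", "table2-equivalent", "baseline interstitial fluid volume")
    plasma_fraction: float = P(0.60, "fraction", "assumed")
    s_bv: float = P(0.25, "dimensionless", "assumed", "blood/ECF compliance partition slope")

    def to_params(self) -> RenalParams:
        return RenalParams(**{
            k: getattr(self, k) for k in RenalParams.__dataclass_fields__
        })


class NeurohormonalConfig(_Section):
    g_md: float = P(0.8, "dimensionless", "calibrated", "renin-secretion macula densa gain")
    s_md: float = P(3.0, "dimensionless", "calibrated")
    a_disinhibition: float = P(4.5, "dimensionless", "calibrated",
                               "AT1-bound AngII feedback strength on renin secretion")
    secretion_cap: float = P(20.0, "dimensionless", "assumed")
    g_ald: float = P(0.8, "dimensionless", "calibrated")
    s_ald: float = P(1.5, "dimensionless", "calibrated")
    t_half_renin: float = P(15.0, "min", "assumed")
    t_half_ang: float = P(4.0, "min", "assumed")
    t_half_ald: float = P(30.0, "min", "assumed")
    g_tgf: float = P(0.7, "dimensionless", "calibrated")
    s_tgf: float = P(2.0, "dimensionless", "calibrated")
    g_myo: float = P(0.9, "dimensionless", "calibrated")
    s_myo: float = P(4.0, "dimensionless", "calibrated")
    s_anp: float = P(1.2, "dimensionless", "calibrated", "ANP sensitivity to the filling surrogate")
    anp_min: float = P(0.2, "dimensionless", "assumed")
    anp_max: float = P(8.0, "dimensionless", "assumed")
    g_vp: float = P(0.8, "dimensionless", "calibrated")
    s_vp: float = P(25.0, "dimensionless", "calibrated")
    anp_driver: Literal["EDP", "EDV"] = P("EDP", "choice", "assumed",
                                          "filling surrogate driving ANP (no atria in the model)")
    g_at1_sys: float = P(0.20, "dimensionless", "calibrated",
                         "AT1-bound AngII effect on peripheral resistance")
    s_at1_sys: float = P(1.5, "dimensionless", "calibrated")
    tau_wba: float = P(720.0, "min", "assumed", "whole-body autoregulation time constant")
    p_wba: float = P(1.5, "dimensionless", "calibrated",
                     "finite autoregulation gain: peripheral-resistance multiplier = (CO/CO0)^p")
    wba_min: float = P(0.25, "dimensionless", "assumed")
    wba_max: float = P(4.0, "dimensionless", "assumed")

    def raas_params(self) -> RAASParams:
        return RAASParams(**{k: getattr(self, k) for k in RAASParams.__dataclass_fields__})

    def signal_params(self) -> SignalParams:
        return SignalParams(**{k: getattr(self, k) for k in SignalParams.__dataclass_fields__})


class SetpointConfig(_Section):
    """Baseline operating values used as feedback setpoints (all calibrated)."""

    EDP0: float = P(8.35, "mmHg", "calibrated", "baseline LV end-diastolic pressure")
    CO0: float = P(4.998, "L/min", "calibrated", "cardiac output setpoint for autoregulation")


class EngineConfig(_Section):
    beat_dt: float = P(0.001, "s", "assumed", "fixed RK4 step of the beat integrator", gt=0)
    macro_step_min: float = P(90.0, "min", "assumed", "slow-timescale macro step", gt=0)
    burst_max_beats: int = P(8, "beats", "assumed", "max beats per burst after initialization")
    burst_tol: float = P(1e-5, "relative", "assumed", "beat-to-beat periodicity tolerance")
    init_max_beats: int = P(600, "beats", "assumed")
    init_tol: float = P(1e-7, "relative", "assumed")
    slow_substeps: int = P(4, "count", "assumed", "sub-steps of the slow-state update per macro step")
    k_ven_target: float = P(1.0, "1/min", "table1", "venous volume coupling rate", gt=0)
    settle_days: float = P(2.0, "days", "assumed", "coupled settling horizon during initialization")
    steady_drift_tol: float = P(0.005, "relative/day", "assumed", "max relative drift accepted as steady")
    seed: int = P(0, "dimensionless", "assumed", "unused; the model is deterministic")


class ModelConfig(_Section):
    cardiac: CardiacConfig = Field(default_factory=CardiacConfig)
    circulation: CirculationConfig = Field(default_factory=CirculationConfig)
    remodeling: RemodelingConfig = Field(default_factory=RemodelingConfig)
    renal: RenalConfig = Field(default_factory=RenalConfig)
    neurohormonal: NeurohormonalConfig = Field(default_factory=NeurohormonalConfig)
    setpoints: SetpointConfig = Field(default_factory=SetpointConfig)
    engine: EngineConfig = Field(default_factory=EngineConfig)

    def remodeling_params(self) -> RemodelingParams:
        return RemodelingParams(
            K_d0=self.remodeling.K_d0, K_l0=self.remodeling.K_l0,
            sigma_peak0=self.remodeling.sigma_peak0, sigma_ED0=self.remodeling.sigma_ED0,
            dD_max=self.remodeling.dD_max, dL_max=self.remodeling.dL_max,
            dD_floor_frac=self.remodeling.dD_floor_frac,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def build_beat_params(
    cfg: ModelConfig,
    *,
    hr: float | None = None,
    vb_target_ml: float | None = None,
    r_art_mult: float = 1.0,
    dp_leak_kpa: float | None = None,
    r_per_mult: float = 1.0,
    v_w_lv: float | None = None,
    v_cav0_lv: float | None = None,
) -> np.ndarray:
    """Pack the beat-kernel parameter vector (beat-level units)."""
    c, ci = cfg.cardiac, cfg.circulation
    p = np.zeros(B.N_PAR)
    hr = hr if hr is not None else c.hr
    p[B.T_CYCLE] = 60.0 / hr
    p[B.VW_LV] = v_w_lv if v_w_lv is not None else cfg.remodeling.V_w0
    p[B.VCAV0_LV] = v_cav0_lv if v_cav0_lv is not None else cfg.remodeling.V_LV0
    p[B.LS_REF] = c.l_s_ref
    p[B.SIGA0_LV] = c.sigma_a0_lv * MMHG_PER_KPA
    p[B.LS_ZERO] = c.l_s_zero
    p[B.LS_SAT] = c.l_s_sat
    p[B.VMAX] = c.v_max
    p[B.TSYS_REF] = c.t_sys_ref
    p[B.CYCLE_REF] = c.cycle_ref
    p[B.CP_LV] = c.c_p * MMHG_PER_KPA
    p[B.KP_LV] = c.k_p
    p[B.WR] = c.w_r
    p[B.VW_RV] = c.V_w_rv
    p[B.VCAV0_RV] = c.V_cav0_rv
    p[B.SIGA0_RV] = c.sigma_a0_rv * MMHG_PER_KPA
    p[B.CP_RV] = c.c_p * MMHG_PER_KPA
    p[B.KP_RV] = c.k_p
    p[B.R_AV] = ci.R_art * r_art_mult * R_CLINICAL_TO_BEAT
    p[B.R_MIT] = ci.R_mitral * R_CLINICAL_TO_BEAT
    if dp_leak_kpa is None:
        dp_leak_kpa = ci.dP_leak
    p[B.DP_LEAK] = dp_leak_kpa * MMHG_PER_KPA if dp_leak_kpa is not None else 1e12
    p[B.R_TRIC] = ci.R_tricuspid * R_CLINICAL_TO_BEAT
    p[B.R_PVAL] = ci.R_pulm_valve * R_CLINICAL_TO_BEAT
    p[B.R_AP] = ci.R_art_per * R_CLINICAL_TO_BEAT
    p[B.I_ART] = ci.I_art * 3.6  # mmHg·min²/L -> mmHg·s²/mL
    p[B.R_PER] = ci.R_per * r_per_mult * R_CLINICAL_TO_BEAT
    p[B.R_PP] = ci.R_pulm * R_CLINICAL_TO_BEAT
    p[B.I_PA] = ci.I_pulm * 3.6
    p[B.C_ART] = ci.C_art
    p[B.C_PER] = ci.C_per
    p[B.C_VEN] = ci.C_ven
    p[B.C_PA] = ci.C_pulm_art
    p[B.C_PV] = ci.C_pulm_ven
    p[B.V0_ART] = ci.V0_art
    p[B.V0_PER] = ci.V0_per
    p[B.V0_VEN] = ci.V0_ven
    p[B.V0_PA] = ci.V0_pulm_art
    p[B.V0_PV] = ci.V0_pulm_ven
    p[B.KVEN] = cfg.engine.k_ven_target / 60.0  # 1/min -> 1/s
    p[B.VB_TARGET] = vb_target_ml if vb_target_ml is not None else cfg.renal.V_b0 * 1000.0
    p[B.TAU_V] = c.tau_vel
    p[B.FVEL_MAX] = c.f_vel_max
    p[B.TPEAK_FRAC] = c.t_peak_frac
    p[B.SIG_ACT_MAX] = c.sigma_act_max * MMHG_PER_KPA
    p[B.SIG_ACT_KNEE] = c.sigma_act_knee * MMHG_PER_KPA
    return p


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a YAML/JSON config; unknown keys are errors.

    With no path, returns the calibrated default configuration.
    """
    if path is None:
        return ModelConfig()
    path = Path(path)
    text = path.read_text()
    data: dict[str, Any]
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text) or {}
    return ModelConfig.model_validate(data)


def dump_config(cfg: ModelConfig, path: str | Path) -> None:
    """Serialize a config to YAML (or JSON by extension), round-trip exact."""
    path = Path(path)
    data = cfg.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
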