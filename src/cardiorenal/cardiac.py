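"""Single-fiber ventricular mechanics.

The ventricle is treated as a thick-walled sphere of contractile tissue in
which one representative myofiber carries the load (the one-fiber
idealization).  Chamber pressure follows from fiber stress and the ratio of
wall volume to cavity volume:

    P = (1/3) * (sigma_f - 2*sigma_mr) * ln(1 + V_w / V_cav)

Fiber strain is the natural strain of the mid-wall material volume, so
sarcomere length maps one-to-one onto cavity volume.  Active stress is the
product of a length factor, a periodic twitch, and a linearized
force-velocity factor; passive stress is exponential in sarcomere
extension.  Left and right ventricles are distinct instances of the same
laws with their own wall volume, unloaded cavity volume, and contractility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FiberState",
    "VentricleState",
    "BeatSummary",
    "ventricular_pressure",
    "sarcomere_kinematics",
    "active_stress",
    "passive_stress",
    "extract_beat_summary",
]


@dataclass
class FiberState:
    """Instantaneous mechanical state of the representative myofiber.

    Stresses in kPa, sarcomere length in μm, time since activation onset in
    seconds.  ``sigma_f`` is always the sum of the active and passive
    components; ``sigma_mr`` is the radial matrix stress entering the
    pressure relation (zero by default).
    """

    sigma_act: float
    sigma_pass: float
    sigma_mr: float
    l_s: float
    t_act: float

    @property
    def sigma_f(self) -> float:
        return self.sigma_act + self.sigma_pass

    def __post_init__(self) -> None:
        if self.l_s <= 0:
            raise ValueError("sarcomere length must be positive")
        if self.sigma_pass < 0:
            raise ValueError("passive stress cannot be negative")


@dataclass
class VentricleState:
    """Chamber-level state: cavity volume, pressure, wall geometry (mL, mmHg)."""

    V_cav: float
    P: float
    V_w: float
    V_cav0: float

    def __post_init__(self) -> None:
        if self.V_cav <= 0 or self.V_w <= 0:
            raise ValueError("cavity and wall volumes must be positive")


@dataclass
class BeatSummary:
    """Per-cardiac-cycle quantities that drive the slow submodels.

    Pressures in mmHg, volumes in mL, stresses in kPa, CO in L/min.
    ``P_ven_mean``/``P_pa_mean``/``P_pv_mean`` are cycle-averaged venous,
    pulmonary arterial and pulmonary venous pressures needed by the renal
    and right-heart bookkeeping; they are not part of the minimal contract
    but are cheap to carry.
    """

    SBP: float
    DBP: float
    MAP: float
    EDP: float
    PSP: float
    EDV: float
    ESV: float
    SV: float
    EF: float
    CO: float
    sigma_f_peak: float
    sigma_f_ED: float
    HR: float
    P_ven_mean: float = float("nan")
    P_pa_mean: float = float("nan")
    P_pv_mean: float = float("nan")
    regurgitant_volume: float = 0.0
    n_beats: int = 1

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def ventricular_pressure(sigma_f: float, sigma_mr: float, V_w: float, V_cav: float) -> float:
    """Chamber pressure from fiber stress (one-fiber law), same unit as stress.

    Parameters are fiber stress, radial matrix stress, wall volume and
    instantaneous cavity volume.  Exact closed form, no approximation.
    """
    if V_cav <= 0 or V_w <= 0:
        raise ValueError("V_cav and V_w must be positive")
    return (sigma_f - 2.0 * sigma_mr) / 3.0 * math.log1p(V_w / V_cav)


def sarcomere_kinematics(
    V_cav: float, V_cav0: float, V_w: float, l_s_ref: float = 2.0
) -> tuple[float, float]:
    """Sarcomere length (μm) and fiber natural strain for a cavity volume.

    The mid-wall fiber natural strain is one third of the natural strain of
    the effective chamber volume ``V_cav + V_w/3``, normalized so that
    ``l_s = l_s_ref`` at the unloaded cavity volume ``V_cav0``.  Strictly
    increasing in ``V_cav``.
    """
    if V_cav <= 0 or V_cav0 <= 0 or V_w <= 0:
        raise ValueError("volumes must be positive")
    eps_f = math.log((V_cav + V_w / 3.0) / (V_cav0 + V_w / 3.0)) / 3.0
    return l_s_ref * math.exp(eps_f), eps_f


def active_stress(
    l_s: float,
    t_act: float,
    dl_s_dt: float,
    cycle_length: float,
    *,
    sigma_a0: float,
    l_s_zero: float = 1.51,
    l_s_sat: float = 2.2,
    v_max: float = 10.0,
    t_sys_ref: float = 0.3,
    cycle_ref: float = 60.0 / 70.0,
    f_vel_max: float = 1.4,
    t_peak_frac: float = 0.5,
    sigma_act_max: float = float("inf"),
    sigma_act_knee: float = float("inf"),
) -> float:
    """Active fiber stress (kPa) at sarcomere length ``l_s`` and twitch time.

    ``sigma_a0`` (kPa) scales the fully activated isometric stress at
    saturating length.  The twitch is a smooth sine-squared rise/decay of
    duration ``t_sys_ref * sqrt(cycle_length / cycle_ref)`` peaking at
    ``t_peak_frac`` of that duration; the length factor is piecewise linear
    between the zero-force length and saturation; the force-velocity factor
    is linear in shortening velocity (μm/s), clamped to ``[0, f_vel_max]``.
    """
    if not 0.0 <= t_act < cycle_length:
        raise ValueError("t_act must lie within [0, cycle_length)")
    t_sys = t_sys_ref * math.sqrt(cycle_length / cycle_ref)
    if t_act >= t_sys:
        return 0.0
    t_peak = t_peak_frac * t_sys
    if t_act < t_peak:
        f_time = math.sin(0.5 * math.pi * t_act / t_peak) ** 2
    else:
        f_time = math.sin(0.5 * math.pi * (t_sys - t_act) / (t_sys - t_peak)) ** 2
    f_len = min(max((l_s - l_s_zero) / (l_s_sat - l_s_zero), 0.0), 1.0)
    f_vel = min(max(1.0 + dl_s_dt / v_max, 0.0), f_vel_max)
    sig_a = sigma_a0 * f_len * f_time * f_vel
    if math.isfinite(sigma_act_knee) and sig_a > sigma_act_knee:
        span = sigma_act_max - sigma_act_knee
        sig_a = sigma_act_knee + span * math.tanh((sig_a - sigma_act_knee) / span)
    return min(sig_a, sigma_act_max)


def passive_stress(
    l_s: float,
    *,
    c_p: float = 0.19,
    k_p: float = 9.0,
    l_s_unloaded: float = 2.0,
) -> float:
    """Passive fiber stress (kPa): exponential in extension beyond unloaded length.

    Zero at and below the unloaded sarcomere length, monotone increasing.
    """
    if l_s <= 0:
        raise ValueError("sarcomere length must be positive")
    if l_s <= l_s_unloaded:
        return 0.0
    return c_p * math.expm1(k_p * (l_s - l_s_unloaded))


def extract_beat_summary(beat_trace: pd.DataFrame, hr: float) -> BeatSummary:
    """Reduce a single-cycle trace to a :class:`BeatSummary`.

    The trace must span exactly one cardiac cycle with columns ``time_s``,
    ``P_lv``, ``P_art``, ``V_lv`` and ``sigma_f`` (kPa); optional columns
    ``P_ven``, ``P_pulm_art``, ``P_pulm_ven`` are averaged when present.
    MAP is the time average of arterial pressure over the cycle; the
    end-diastole event is the sample of maximum LV volume (mitral inflow
    has just ceased there, and with strictly periodic activation and no
    atria it coincides with activation onset).
    """
    required = {"time_s", "P_lv", "P_art", "V_lv", "sigma_f"}
    missing = required - set(beat_trace.columns)
    if missing:
        raise ValueError(f"trace is missing columns: {sorted(missing)}")
    t = beat_trace["time_s"].to_numpy(float)
    if len(t) < 3:
        raise ValueError("trace shorter than one cycle")
    cycle = 60.0 / hr
    span = t[-1] - t[0]
    if span < 0.9 * cycle or span > 1.1 * cycle:
        raise ValueError("trace does not span one cardiac cycle")

    p_art = beat_trace["P_art"].to_numpy(float)
    p_lv = beat_trace["P_lv"].to_numpy(float)
    v_lv = beat_trace["V_lv"].to_numpy(float)
    sig = beat_trace["sigma_f"].to_numpy(float)

    def tavg(x: np.ndarray) -> float:
        return float(np.trapezoid(x, t) / span)

    i_ed = int(np.argmax(v_lv))
    edv, esv = float(v_lv[i_ed]), float(v_lv.min())
    sv = edv - esv
    out = BeatSummary(
        SBP=float(p_art.max()),
        DBP=float(p_art.min()),
        MAP=tavg(p_art),
        EDP=float(p_lv[i_ed]),
        PSP=float(p_lv.max()),
        EDV=edv,
        ESV=esv,
        SV=sv,
        EF=sv / edv,
        CO=sv * hr / 1000.0,
        sigma_f_peak=float(sig.max()),
        sigma_f_ED=float(sig[i_ed]),
        HR=hr,
    )
    for col, attr in (
        ("P_ven", "P_ven_mean"),
        ("P_pulm_art", "P_pa_mean"),
        ("P_pulm_ven", "P_pv_mean"),
    ):
        if col in beat_trace.columns:
            setattr(out, attr, tavg(beat_trace[col].to_numpy(float)))
    return out
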