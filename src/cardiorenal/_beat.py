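"""Compiled beat-level integrator.

Fixed-step RK4 over the fast (sub-second) state of the coupled
ventricle/circulation system.  This kernel mirrors the closed-form laws in
:mod:`cardiorenal.cardiac` and :mod:`cardiorenal.circulation` — the pure
functions there are the tested contract, and the test suite checks the
kernel against them point-by-point — but runs compiled because a year of
slow-timescale simulation needs tens of thousands of beats.

Internal units: mL, s, mmHg (stresses too); resistances mmHg·s/mL.

Fast state vector (length 11):
  0..6  compartment volumes  V_lv, V_art, V_per, V_ven, V_rv, V_pa, V_pv
  7, 8  inertial flows       Q_art_out, Q_pulm_art_out (mL/s)
  9,10  filtered sarcomere velocity dls/dt for LV and RV (μm/s)

The venous compartment carries the renal coupling term
k_ven * (V_ven_target - V_ven) with V_ven_target = V_b - sum(other
compartments), which pins total circulating volume to the renal blood
volume on the ~1 min timescale.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# --- parameter vector layout -------------------------------------------------
T_CYCLE = 0
VW_LV = 1
VCAV0_LV = 2
LS_REF = 3
SIGA0_LV = 4
LS_ZERO = 5
LS_SAT = 6
VMAX = 7
TSYS_REF = 8
CYCLE_REF = 9
CP_LV = 10
KP_LV = 11
WR = 12
VW_RV = 13
VCAV0_RV = 14
SIGA0_RV = 15
CP_RV = 16
KP_RV = 17
R_AV = 18
R_MIT = 19
DP_LEAK = 20
R_TRIC = 21
R_PVAL = 22
R_AP = 23
I_ART = 24
R_PER = 25
R_PP = 26
I_PA = 27
C_ART = 28
C_PER = 29
C_VEN = 30
C_PA = 31
C_PV = 32
V0_ART = 33
V0_PER = 34
V0_VEN = 35
V0_PA = 36
V0_PV = 37
KVEN = 38
VB_TARGET = 39
TAU_V = 40
FVEL_MAX = 41
TPEAK_FRAC = 42
SIG_ACT_MAX = 43
SIG_ACT_KNEE = 44
N_PAR = 45

# --- summary vector layout ---------------------------------------------------
S_SBP = 0
S_DBP = 1
S_MAP = 2
S_PSP = 3
S_EDP = 4
S_EDV = 5
S_ESV = 6
S_SV = 7
S_EF = 8
S_CO = 9
S_SIGPEAK = 10
S_SIGED = 11
S_PVEN = 12
S_PPA = 13
S_PPV = 14
S_HR = 15
S_NBEATS = 16
S_REGURG = 17
S_VTOT = 18
S_PPER = 19
N_SUM = 20

# trace column layout (simulate_trace)
TRACE_COLS = (
    "time_s", "P_lv", "P_rv", "P_art", "P_ven", "P_pulm_art", "P_pulm_ven",
    "V_lv", "V_rv", "sigma_f", "sigma_act", "sigma_pass", "Q_mitral",
)


@njit(cache=True)
def _ventricle(v_cav, vs, t_act, vw, vcav0, siga0, cp, kp, p):
    """Return (P, sigma_act, sigma_pass, l_s) for one ventricle (mmHg)."""
    ls_ref = p[LS_REF]
    eps = math.log((v_cav + vw / 3.0) / (vcav0 + vw / 3.0)) / 3.0
    l_s = ls_ref * math.exp(eps)
    # active stress
    t_sys = p[TSYS_REF] * math.sqrt(p[T_CYCLE] / p[CYCLE_REF])
    sig_a = 0.0
    if t_act < t_sys:
        t_peak = p[TPEAK_FRAC] * t_sys
        if t_act < t_peak:
            f_time = math.sin(0.5 * math.pi * t_act / t_peak) ** 2
        else:
            f_time = math.sin(0.5 * math.pi * (t_sys - t_act) / (t_sys - t_peak)) ** 2
        f_len = (l_s - p[LS_ZERO]) / (p[LS_SAT] - p[LS_ZERO])
        if f_len < 0.0:
            f_len = 0.0
        elif f_len > 1.0:
            f_len = 1.0
        f_vel = 1.0 + vs / p[VMAX]
        if f_vel < 0.0:
            f_vel = 0.0
        elif f_vel > p[FVEL_MAX]:
            f_vel = p[FVEL_MAX]
        sig_a = siga0 * f_len * f_time * f_vel
        # graded contractile reserve: linear below the knee, saturating
        # smoothly toward the maximal active tension above it
        knee = p[SIG_ACT_KNEE]
        span = p[SIG_ACT_MAX] - knee
        if sig_a > knee:
            sig_a = knee + span * math.tanh((sig_a - knee) / span)
    # passive stress (unloaded at l_s = ls_ref)
    sig_p = 0.0
    if l_s > ls_ref:
        sig_p = cp * (math.exp(kp * (l_s - ls_ref)) - 1.0)
    sig_f = sig_a + sig_p
    lnterm = math.log(1.0 + vw / v_cav)
    # sigma_mr = -w_r * P  =>  P = sigma_f*ln/3 / (1 - 2*w_r*ln/3)
    pres = sig_f * lnterm / 3.0 / (1.0 - 2.0 * p[WR] * lnterm / 3.0)
    return pres, sig_a, sig_p, l_s


@njit(cache=True)
def _rhs(t_act, y, p, dy):
    """Fill dy; return instantaneous pressures/stresses for accumulation."""
    p_lv, sa_lv, sp_lv, ls_lv = _ventricle(
        y[0], y[9], t_act, p[VW_LV], p[VCAV0_LV], p[SIGA0_LV], p[CP_LV], p[KP_LV], p
    )
    p_rv, sa_rv, sp_rv, ls_rv = _ventricle(
        y[4], y[10], t_act, p[VW_RV], p[VCAV0_RV], p[SIGA0_RV], p[CP_RV], p[KP_RV], p
    )
    p_art = (y[1] - p[V0_ART]) / p[C_ART]
    p_per = (y[2] - p[V0_PER]) / p[C_PER]
    p_ven = (y[3] - p[V0_VEN]) / p[C_VEN]
    p_pa = (y[5] - p[V0_PA]) / p[C_PA]
    p_pv = (y[6] - p[V0_PV]) / p[C_PV]

    # valves (ideal diodes; mitral may leak above the threshold)
    q_av = (p_lv - p_art) / p[R_AV] if p_lv > p_art else 0.0
    if p_pv > p_lv:
        q_mit = (p_pv - p_lv) / p[R_MIT]
    elif (p_lv - p_pv) > p[DP_LEAK]:
        q_mit = (p_pv - p_lv) / p[R_MIT]  # negative back-leak
    else:
        q_mit = 0.0
    q_tric = (p_ven - p_rv) / p[R_TRIC] if p_ven > p_rv else 0.0
    q_pval = (p_rv - p_pa) / p[R_PVAL] if p_rv > p_pa else 0.0

    q_ao = y[7]
    q_po = y[8]
    q_per_out = (p_per - p_ven) / p[R_PER]

    v_ven_target = p[VB_TARGET] - (y[0] + y[1] + y[2] + y[4] + y[5] + y[6])

    dy[0] = q_mit - q_av
    dy[1] = q_av - q_ao
    dy[2] = q_ao - q_per_out
    dy[3] = q_per_out - q_tric + p[KVEN] * (v_ven_target - y[3])
    dy[4] = q_tric - q_pval
    dy[5] = q_pval - q_po
    dy[6] = q_po - q_mit
    dy[7] = (p_art - p_per - p[R_AP] * q_ao) / p[I_ART]
    dy[8] = (p_pa - p_pv - p[R_PP] * q_po) / p[I_PA]

    # sarcomere velocity filters
    v_inst_lv = ls_lv / 3.0 * dy[0] / (y[0] + p[VW_LV] / 3.0)
    v_inst_rv = ls_rv / 3.0 * dy[4] / (y[4] + p[VW_RV] / 3.0)
    dy[9] = (v_inst_lv - y[9]) / p[TAU_V]
    dy[10] = (v_inst_rv - y[10]) / p[TAU_V]

    return p_lv, p_rv, p_art, p_per, p_ven, p_pa, p_pv, sa_lv, sp_lv, q_mit


@njit(cache=True)
def _step_rk4(t_act, y, p, dt, k1, k2, k3, k4, tmp):
    aux = _rhs(t_act, y, p, k1)
    for i in range(y.size):
        tmp[i] = y[i] + 0.5 * dt * k1[i]
    _rhs(t_act + 0.5 * dt, tmp, p, k2)
    for i in range(y.size):
        tmp[i] = y[i] + 0.5 * dt * k2[i]
    _rhs(t_act + 0.5 * dt, tmp, p, k3)
    for i in range(y.size):
        tmp[i] = y[i] + dt * k3[i]
    _rhs(t_act + dt, tmp, p, k4)
    for i in range(y.size):
        y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    return aux


@njit(cache=True)
def simulate_burst(y, p, max_beats, tol, dt, summary):
    """Integrate beats until beat-to-beat periodicity (or max_beats).

    ``y`` is advanced in place; ``summary`` (length N_SUM) receives the
    last simulated beat.  Returns the number of beats run.  Beats start at
    activation onset, so the state at t_act = 0 is the end-diastole sample.
    """
    t_cycle = p[T_CYCLE]
    n_steps = int(round(t_cycle / dt))
    dt_eff = t_cycle / n_steps
    k1 = np.empty(11)
    k2 = np.empty(11)
    k3 = np.empty(11)
    k4 = np.empty(11)
    tmp = np.empty(11)
    prev_edv = -1.0
    prev_sv = -1.0
    n_done = 0
    for beat in range(max_beats):
        # end-diastole sample at activation onset
        aux0 = _rhs(0.0, y, p, k1)
        edp = aux0[0]
        edv = y[0]
        sig_ed = aux0[7] + aux0[8]
        sbp = -1e30
        dbp = 1e30
        psp = -1e30
        sigpeak = -1e30
        esv = 1e30
        map_acc = 0.0
        pven_acc = 0.0
        ppa_acc = 0.0
        ppv_acc = 0.0
        pper_acc = 0.0
        regurg = 0.0
        t_act = 0.0
        for _ in range(n_steps):
            aux = _step_rk4(t_act, y, p, dt_eff, k1, k2, k3, k4, tmp)
            t_act += dt_eff
            p_lv = aux[0]
            p_art = aux[2]
            if p_art > sbp:
                sbp = p_art
            if p_art < dbp:
                dbp = p_art
            if p_lv > psp:
                psp = p_lv
            sig = aux[7] + aux[8]
            if sig > sigpeak:
                sigpeak = sig
            if y[0] < esv:
                esv = y[0]
            map_acc += p_art
            pper_acc += aux[3]
            pven_acc += aux[4]
            ppa_acc += aux[5]
            ppv_acc += aux[6]
            if aux[9] < 0.0:
                regurg -= aux[9] * dt_eff
        n_done = beat + 1
        sv = edv - esv
        hr = 60.0 / t_cycle
        summary[S_SBP] = sbp
        summary[S_DBP] = dbp
        summary[S_MAP] = map_acc / n_steps
        summary[S_PSP] = psp
        summary[S_EDP] = edp
        summary[S_EDV] = edv
        summary[S_ESV] = esv
        summary[S_SV] = sv
        summary[S_EF] = sv / edv if edv > 0 else 0.0
        summary[S_CO] = sv * hr / 1000.0
        summary[S_SIGPEAK] = sigpeak
        summary[S_SIGED] = sig_ed
        summary[S_PVEN] = pven_acc / n_steps
        summary[S_PPA] = ppa_acc / n_steps
        summary[S_PPV] = ppv_acc / n_steps
        summary[S_HR] = hr
        summary[S_NBEATS] = n_done
        summary[S_REGURG] = regurg
        summary[S_VTOT] = y[0] + y[1] + y[2] + y[3] + y[4] + y[5] + y[6]
        summary[S_PPER] = pper_acc / n_steps
        if prev_edv > 0.0:
            d_edv = abs(edv - prev_edv) / max(edv, 1e-9)
            d_sv = abs(sv - prev_sv) / max(abs(sv), 1e-9)
            if d_edv < tol and d_sv < tol:
                break
        prev_edv = edv
        prev_sv = sv
    return n_done


@njit(cache=True)
def simulate_trace(y, p, dt, out):
    """Record one full beat into ``out`` (n_steps+1 rows, TRACE_COLS order)."""
    t_cycle = p[T_CYCLE]
    n_steps = out.shape[0] - 1
    dt_eff = t_cycle / n_steps
    k1 = np.empty(11)
    k2 = np.empty(11)
    k3 = np.empty(11)
    k4 = np.empty(11)
    tmp = np.empty(11)
    t_act = 0.0
    for i in range(n_steps + 1):
        aux = _rhs(t_act, y, p, k1)
        out[i, 0] = t_act
        out[i, 1] = aux[0]
        out[i, 2] = aux[1]
        out[i, 3] = aux[2]
        out[i, 4] = aux[4]
        out[i, 5] = aux[5]
        out[i, 6] = aux[6]
        out[i, 7] = y[0]
        out[i, 8] = y[4]
        out[i, 9] = aux[7] + aux[8]
        out[i, 10] = aux[7]
        out[i, 11] = aux[8]
        out[i, 12] = aux[9]
        if i < n_steps:
            _step_rk4(t_act, y, p, dt_eff, k1, k2, k3, k4, tmp)
            t_act += dt_eff
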