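"""RAAS cascade, ANP, vasopressin and intrinsic regulatory signals.

All hormone levels and feedback signals are dimensionless, normalized so
that every quantity equals 1 at the baseline operating point (absolute
concentrations are out of scope).  Feedback shapes are bounded normalized
sigmoids: ``1 + gain * tanh(slope * (x - 1))`` of the normalized input, so
signals stay positive under arbitrary bounded inputs and are exactly 1 at
setpoint.

Renin secretion falls with macula densa sodium flow and is strongly
disinhibited when AT1-bound angiotensin II falls — this makes the
closed-loop map from secretion inhibition to steady-state plasma renin
activity (PRA) strongly concave: blocking 90% of secretion yields well
under a 90% drop in PRA once the feedback re-opens the loop.  PRA is
identified with the (normalized) plasma renin concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "RAASParams",
    "SignalParams",
    "RAASState",
    "FeedbackSignals",
    "bounded_effect",
    "renin_secretion",
    "angiotensin_cascade",
    "aldosterone_mr",
    "anp_signal",
    "vasopressin_signal",
    "intrinsic_signals",
    "raas_steady_state",
    "raas_derivatives",
]


def bounded_effect(x: float, gain: float, slope: float) -> float:
    """Normalized bounded sigmoid: 1 at x=1, range (1-gain, 1+gain).

    The workhorse shape for every feedback effect multiplier; ``gain < 1``
    guarantees positivity.
    """
    return 1.0 + gain * math.tanh(slope * (x - 1.0))


@dataclass
class RAASParams:
    """Renin-angiotensin-aldosterone constants (all normalized).

    ``a_disinhibition`` sets the strength of the AT1-bound-AngII feedback on
    renin secretion (exp law, capped at ``secretion_cap``); ``g_md``/``s_md``
    shape the macula-densa dependence.  Half-lives (minutes) are used only
    by the explicit first-order kinetics; the engine holds hormones at
    their quasi-steady state because macro-steps are much longer.
    """

    g_md: float = 0.8
    s_md: float = 3.0
    a_disinhibition: float = 4.5
    secretion_cap: float = 20.0
    g_ald: float = 0.8
    s_ald: float = 1.5
    t_half_renin: float = 15.0
    t_half_ang: float = 4.0
    t_half_ald: float = 30.0


@dataclass
class SignalParams:
    """Shapes of the intrinsic feedback signals (all normalized inputs)."""

    g_tgf: float = 0.7
    s_tgf: float = 2.0
    g_myo: float = 0.9
    s_myo: float = 4.0
    s_anp: float = 1.2
    anp_min: float = 0.2
    anp_max: float = 8.0
    g_vp: float = 0.8
    s_vp: float = 25.0


@dataclass
class RAASState:
    PRC: float = 1.0
    PRA: float = 1.0
    AngI: float = 1.0
    AngII: float = 1.0
    AT1_AngII: float = 1.0
    AT2_AngII: float = 1.0
    aldosterone: float = 1.0
    MR_occupancy: float = 1.0


@dataclass
class FeedbackSignals:
    TGF: float = 1.0
    myogenic: float = 1.0
    pressure_natriuresis: float = 1.0
    whole_body_autoreg: float = 1.0
    ANP: float = 1.0
    vasopressin: float = 1.0


def renin_secretion(
    macula_densa_na_flow: float,
    at1_angii: float,
    inhibition_fraction: float,
    params: RAASParams | None = None,
) -> float:
    """Normalized renin secretion rate.

    Decreasing in macula densa Na flow, strongly increasing as AT1-bound
    AngII falls below 1 (feedback disinhibition), scaled by
    ``1 - inhibition_fraction`` (pharmacological secretion block).
    """
    p = params or RAASParams()
    if not 0.0 <= inhibition_fraction <= 1.0:
        raise ValueError("inhibition fraction must lie in [0, 1]")
    nu_md = bounded_effect(macula_densa_na_flow, p.g_md, -p.s_md)
    nu_at1 = min(math.exp(p.a_disinhibition * (1.0 - at1_angii)), p.secretion_cap)
    return nu_md * nu_at1 * (1.0 - inhibition_fraction)


def angiotensin_cascade(
    prc: float, ace_activity: float = 1.0, at1_block_fraction: float = 0.0
) -> tuple[float, float, float, float]:
    """Steady-state (AngI, AngII, AT1_AngII, AT2_AngII) for a renin level.

    Unity-gain linear kinetic chain normalized to baseline: production of
    AngI is proportional to PRC, conversion to AngII to ACE activity, and
    AT1 binding is scaled by the unblocked receptor fraction.
    """
    if not 0.0 <= at1_block_fraction <= 1.0:
        raise ValueError("AT1 block fraction must lie in [0, 1]")
    ang_i = prc
    ang_ii = ang_i * ace_activity
    return ang_i, ang_ii, ang_ii * (1.0 - at1_block_fraction), ang_ii


def aldosterone_mr(at1_angii: float, params: RAASParams | None = None) -> tuple[float, float]:
    """Aldosterone level and mineralocorticoid-receptor occupancy.

    Aldosterone secretion rises with AT1-bound AngII; MR occupancy is a
    saturating (Michaelis-type) function of aldosterone, normalized to 1 at
    baseline.  Plasma potassium is a placeholder (normal, no effect).
    """
    p = params or RAASParams()
    ald = bounded_effect(at1_angii, p.g_ald, p.s_ald)
    mr = 2.0 * ald / (1.0 + ald)
    return ald, mr


def anp_signal(filling_surrogate: float, params: SignalParams | None = None) -> float:
    """ANP level from the normalized filling surrogate (LV EDP by default).

    The model has no atria, so LV end-diastolic pressure stands in for
    atrial stretch.  Exponential in the relative filling signal, clamped.
    """
    p = params or SignalParams()
    x = math.exp(p.s_anp * (filling_surrogate - 1.0))
    return min(max(x, p.anp_min), p.anp_max)


def vasopressin_signal(plasma_na_norm: float, params: SignalParams | None = None) -> float:
    """Vasopressin from normalized plasma Na concentration (steep sigmoid)."""
    p = params or SignalParams()
    return bounded_effect(plasma_na_norm, p.g_vp, p.s_vp)


def intrinsic_signals(
    macula_densa_na_flow: float,
    preafferent_pressure: float,
    rihp: float,
    cardiac_output: float,
    params: SignalParams | None = None,
) -> FeedbackSignals:
    """Intrinsic regulatory signals from their normalized inputs.

    TGF rises with macula densa Na flow (afferent constriction); the
    myogenic signal rises with preafferent pressure; the pressure-
    natriuresis signal is the normalized renal interstitial hydrostatic
    pressure itself; the whole-body autoregulation multiplier is reported
    as the instantaneous (non-integrated) response to cardiac output.
    """
    p = params or SignalParams()
    return FeedbackSignals(
        TGF=bounded_effect(macula_densa_na_flow, p.g_tgf, p.s_tgf),
        myogenic=bounded_effect(preafferent_pressure, p.g_myo, p.s_myo),
        pressure_natriuresis=rihp,
        whole_body_autoreg=bounded_effect(cardiac_output, 0.9, 4.0),
    )


def raas_steady_state(
    macula_densa_na_flow: float,
    at1_block_fraction: float = 0.0,
    inhibition_fraction: float = 0.0,
    ace_activity: float = 1.0,
    params: RAASParams | None = None,
) -> RAASState:
    """Closed-form quasi-steady RAAS state at fixed macula densa Na flow.

    Solves the scalar fixed point PRC = secretion(MD, AT1(PRC)); secretion
    is strictly decreasing in PRC through the AT1 feedback, so the root is
    unique.
    """
    p = params or RAASParams()

    def resid(prc: float) -> float:
        _, _, at1, _ = angiotensin_cascade(prc, ace_activity, at1_block_fraction)
        return renin_secretion(macula_densa_na_flow, at1, inhibition_fraction, p) - prc

    lo, hi = 1e-9, p.secretion_cap * 2.0
    if resid(lo) <= 0.0:
        prc = lo
    elif resid(hi) >= 0.0:
        prc = hi
    else:
        prc = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-12)
    ang_i, ang_ii, at1, at2 = angiotensin_cascade(prc, ace_activity, at1_block_fraction)
    ald, mr = aldosterone_mr(at1, p)
    return RAASState(
        PRC=prc, PRA=prc, AngI=ang_i, AngII=ang_ii,
        AT1_AngII=at1, AT2_AngII=at2, aldosterone=ald, MR_occupancy=mr,
    )


def raas_derivatives(
    state: RAASState,
    macula_densa_na_flow: float,
    at1_block_fraction: float = 0.0,
    inhibition_fraction: float = 0.0,
    ace_activity: float = 1.0,
    params: RAASParams | None = None,
) -> tuple[float, float, float]:
    """First-order kinetics (d/dt in 1/min) for PRC, AngI, AngII.

    Provided for sub-macro-step hormone dynamics; each species relaxes to
    its production level with rate ln2 / half-life.  The engine defaults to
    the quasi-steady solution because its macro-step far exceeds these
    half-lives.
    """
    p = params or RAASParams()
    k_renin = math.log(2.0) / p.t_half_renin
    k_ang = math.log(2.0) / p.t_half_ang
    sec = renin_secretion(
        macula_densa_na_flow, state.AT1_AngII, inhibition_fraction, p
    )
    d_prc = k_renin * (sec - state.PRC)
    d_angi = k_ang * (state.PRC - state.AngI)
    d_angii = k_ang * (state.AngI * ace_activity - state.AngII)
    return d_prc, d_angi, d_angii
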