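"""Renal hemodynamics, glomerular filtration, tubular handling, body fluids.

The kidney sees the circulation through mean arterial pressure (perfusion)
and mean venous pressure (outflow), and returns sodium and water excretion,
which integrate into total body sodium and extracellular fluid volume and
hence blood volume.  The vasculature is a series resistance network
(preafferent, afferent, efferent, peritubular/venous); filtration is a
Starling balance at the glomerulus; the nephron is lumped into three
segments (proximal tubule; loop+distal with the macula densa at its exit;
connecting tubule/collecting duct).

All feedback effects enter as normalized multipliers equal to 1 at the
baseline operating point.  Baseline-derived constants (filtration
coefficient, peritubular resistance, segment setpoints) are computed from
the parameter set so that at ``MAP0`` with all signals at 1 the kidney
delivers exactly RBF0, GFR0 and excretion = intake: the baseline is a fixed
point by construction.

Glucose is carried at normoglycemia as a pass-through (fully reabsorbed,
zero urinary glucose); there is no SGLT pharmacology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .neurohormonal import bounded_effect

__all__ = [
    "RenalParams",
    "RenalBaseline",
    "RenalVascularState",
    "NephronState",
    "BodyFluidState",
    "RenalState",
    "renal_hemodynamics",
    "glomerular_filtration",
    "sodium_handling",
    "water_handling",
    "fluid_balance",
    "renal_operating_point",
]


@dataclass
class RenalParams:
    """Renal and body-fluid constants.

    Pressures mmHg, flows mL/min (RBF in L/min), Na in mEq.  ``MAP0`` and
    ``P_ven0`` are the calibrated baseline mean arterial and venous
    pressures of the circulation; segment resistances are chosen to give
    physiologic intrarenal pressures (glomerular ~60 mmHg, peritubular
    ~16 mmHg) at that operating point.
    """

    MAP0: float = 85.0
    P_ven0: float = 4.0
    RBF0: float = 1.0            # L/min
    GFR0: float = 100.0          # mL/min
    P_bowman: float = 18.0
    pi_gc: float = 28.0
    R_preaff0: float = 14.0
    R_aff0: float = 11.0
    R_eff0: float = 44.0
    # tubular fractions (sodium)
    f_pt0: float = 0.70
    f_ld0: float = 0.80
    # tubular fractions (water)
    f_ldw0: float = 0.80
    # intakes
    na_intake0: float = 100.0 / 1440.0   # mEq/min (100 mmol/day)
    water_intake0: float = 1.0           # mL/min
    c_na0: float = 140.0                 # mEq/L
    urine_min: float = 0.05              # mL/min obligate urine flow
    # pressure natriuresis
    RIHP0: float = 4.0
    rihp_p_gain: float = 4.0
    rihp_q_gain: float = 0.5
    g_pn_pt: float = 0.12
    s_pn_pt: float = 2.0
    g_pn_cd: float = 0.05
    s_pn_cd: float = 3.0
    # hormonal effects on tubules
    g_at1_pt: float = 0.08
    s_at1_pt: float = 1.5
    g_mr_cd: float = 0.02
    s_mr_cd: float = 2.0
    g_anp_cd: float = 0.02
    s_anp_cd: float = 1.0
    g_vp_cdw: float = 0.12
    s_vp_cdw: float = 2.0
    # hormonal effects on renal vasculature
    g_at1_eff: float = 0.35
    s_at1_eff: float = 1.5
    g_at1_pre: float = 0.15
    s_at1_pre: float = 1.5
    g_at1_aff: float = 0.10
    s_at1_aff: float = 1.5
    # body fluids
    V_b0: float = 4.95           # L
    V_isf0: float = 12.0         # L
    plasma_fraction: float = 0.60
    s_bv: float = 0.25           # dV_b / dV_ecf along the compliance curve


@dataclass
class RenalBaseline:
    """Constants derived from :class:`RenalParams` so baseline closes exactly."""

    K_f: float
    R_ptc0: float
    P_gc0: float
    P_ptc0: float
    P_pre0: float
    phi_md0: float
    f_cd0: float
    q_dist_w0: float
    f_cdw0: float
    V_ecf0: float
    body_na0: float

    @classmethod
    def from_params(cls, p: RenalParams) -> "RenalBaseline":
        r_total = (p.MAP0 - p.P_ven0) / p.RBF0
        r_ptc = r_total - (p.R_preaff0 + p.R_aff0 + p.R_eff0)
        if r_ptc <= 0:
            raise ValueError("segment resistances exceed the total renal resistance")
        p_gc = p.MAP0 - p.RBF0 * (p.R_preaff0 + p.R_aff0)
        net = p_gc - p.P_bowman - p.pi_gc
        if net <= 0:
            raise ValueError("baseline net filtration pressure must be positive")
        k_f = p.GFR0 / net
        p_ptc = p_gc - p.RBF0 * p.R_eff0
        filtered0 = p.GFR0 * p.c_na0 / 1000.0
        phi_md0 = filtered0 * (1.0 - p.f_pt0) * (1.0 - p.f_ld0)
        if p.na_intake0 >= phi_md0:
            raise ValueError("baseline Na intake exceeds distal delivery")
        f_cd0 = 1.0 - p.na_intake0 / phi_md0
        q_dist_w0 = p.GFR0 * (1.0 - p.f_pt0) * (1.0 - p.f_ldw0)
        if p.water_intake0 >= q_dist_w0:
            raise ValueError("baseline water intake exceeds distal water delivery")
        f_cdw0 = 1.0 - p.water_intake0 / q_dist_w0
        plasma0 = p.plasma_fraction * p.V_b0
        v_ecf0 = plasma0 + p.V_isf0
        return cls(
            K_f=k_f, R_ptc0=r_ptc, P_gc0=p_gc, P_ptc0=p_ptc,
            P_pre0=p.MAP0 - p.RBF0 * p.R_preaff0,
            phi_md0=phi_md0, f_cd0=f_cd0, q_dist_w0=q_dist_w0, f_cdw0=f_cdw0,
            V_ecf0=v_ecf0, body_na0=p.c_na0 * v_ecf0,
        )


@dataclass
class RenalVascularState:
    R_preaff: float
    R_aff: float
    R_eff: float
    RBF: float
    P_gc: float
    P_preaff: float
    P_ptc: float
    RIHP: float


@dataclass
class NephronState:
    GFR: float
    filtered_na: float
    f_pt: float
    f_ld: float
    f_cd: float
    phi_md: float
    na_excretion: float
    urine_flow: float


@dataclass
class BodyFluidState:
    """Whole-body Na and extracellular fluid; blood volume follows the
    (linear, monotone) blood/interstitium compliance partition."""

    body_na: float
    V_ecf: float

    def blood_volume(self, p: RenalParams, base: RenalBaseline) -> float:
        return p.V_b0 + p.s_bv * (self.V_ecf - base.V_ecf0)

    def interstitial_volume(self, p: RenalParams, base: RenalBaseline) -> float:
        plasma = p.plasma_fraction * p.V_b0 + p.s_bv * (self.V_ecf - base.V_ecf0)
        return self.V_ecf - plasma

    def plasma_na(self) -> float:
        return self.body_na / self.V_ecf


@dataclass
class RenalState:
    vasc: RenalVascularState
    nephron: NephronState
    mu_tgf: float
    mu_myo: float
    rihp_norm: float


def renal_hemodynamics(
    MAP: float,
    P_ven: float,
    p: RenalParams,
    base: RenalBaseline,
    mu_tgf: float = 1.0,
    mu_myo: float = 1.0,
    at1: float = 1.0,
    preaff_mult: float = 1.0,
) -> RenalVascularState:
    """Series-network renal hemodynamics for given feedback multipliers.

    The myogenic signal scales the preafferent resistance, TGF the afferent,
    and AT1-bound AngII constricts all three upstream segments (the
    efferent most strongly).  RIHP is computed from the peritubular
    capillary pressure alone here; the tubular-flow contribution is added by
    the operating-point solver.
    """
    if MAP <= P_ven:
        raise ValueError("MAP must exceed renal venous pressure")
    r_pre = p.R_preaff0 * mu_myo * bounded_effect(at1, p.g_at1_pre, p.s_at1_pre) * preaff_mult
    r_aff = p.R_aff0 * mu_tgf * bounded_effect(at1, p.g_at1_aff, p.s_at1_aff)
    r_eff = p.R_eff0 * bounded_effect(at1, p.g_at1_eff, p.s_at1_eff)
    r_total = r_pre + r_aff + r_eff + base.R_ptc0
    rbf = (MAP - P_ven) / r_total
    p_pre = MAP - rbf * r_pre
    p_gc = MAP - rbf * (r_pre + r_aff)
    p_ptc = p_gc - rbf * r_eff
    # The pressure input to RIHP is taken at the arterial-side operating
    # point (reference venous pressure): venous congestion then acts on
    # sodium handling only through reduced RBF/GFR (retention), which keeps
    # long-term arterial pressure kidney-determined.
    rbf_ref = (MAP - p.P_ven0) / r_total
    p_ptc_ref = MAP - rbf_ref * (r_pre + r_aff + r_eff)
    rihp = p.RIHP0 * (1.0 + p.rihp_p_gain * (p_ptc_ref / base.P_ptc0 - 1.0))
    return RenalVascularState(
        R_preaff=r_pre, R_aff=r_aff, R_eff=r_eff, RBF=rbf,
        P_gc=p_gc, P_preaff=p_pre, P_ptc=p_ptc, RIHP=max(rihp, 0.1),
    )


def glomerular_filtration(P_gc: float, P_bowman: float, pi_gc: float, K_f: float) -> float:
    """Single-nephron-lumped GFR (mL/min), Starling balance, clamped at 0."""
    if K_f <= 0:
        raise ValueError("filtration coefficient must be positive")
    return K_f * max(P_gc - P_bowman - pi_gc, 0.0)


def sodium_handling(
    filtered_na: float,
    p: RenalParams,
    base: RenalBaseline,
    at1: float = 1.0,
    mr: float = 1.0,
    anp: float = 1.0,
    rihp_norm: float = 1.0,
    pt_mult: float = 1.0,
) -> tuple[float, float, float, float]:
    """Segmental Na handling: returns (f_pt, f_cd, phi_md, excretion).

    Proximal reabsorption rises with AT1-bound AngII and falls with the
    pressure-natriuresis signal; the collecting segment follows MR
    occupancy (up), ANP (down) and pressure natriuresis (down).  Fractions
    are clamped to [0, 1].
    """
    if filtered_na < 0:
        raise ValueError("filtered load cannot be negative")
    f_pt = p.f_pt0 * bounded_effect(at1, p.g_at1_pt, p.s_at1_pt) \
        * bounded_effect(rihp_norm, p.g_pn_pt, -p.s_pn_pt) * pt_mult
    f_pt = min(max(f_pt, 0.0), 1.0)
    phi_md = filtered_na * (1.0 - f_pt) * (1.0 - p.f_ld0)
    f_cd = base.f_cd0 * bounded_effect(mr, p.g_mr_cd, p.s_mr_cd) \
        * bounded_effect(anp, p.g_anp_cd, -p.s_anp_cd) \
        * bounded_effect(rihp_norm, p.g_pn_cd, -p.s_pn_cd)
    f_cd = min(max(f_cd, 0.0), 1.0)
    excretion = phi_md * (1.0 - f_cd)
    return f_pt, f_cd, phi_md, excretion


def water_handling(
    gfr: float,
    f_pt: float,
    p: RenalParams,
    base: RenalBaseline,
    vasopressin: float = 1.0,
) -> float:
    """Urine flow (mL/min).

    Water follows sodium isotonically in the proximal tubule, a fixed
    fraction is reclaimed along the loop/distal segment, and collecting-duct
    water reabsorption scales with vasopressin.  An obligate minimum urine
    flow is enforced.
    """
    if gfr < 0:
        raise ValueError("GFR cannot be negative")
    if gfr == 0.0:
        return 0.0
    q_dist = gfr * (1.0 - f_pt) * (1.0 - p.f_ldw0)
    f_cdw = base.f_cdw0 * bounded_effect(vasopressin, p.g_vp_cdw, p.s_vp_cdw)
    f_cdw = min(max(f_cdw, 0.0), 1.0)
    return max(q_dist * (1.0 - f_cdw), p.urine_min)


def fluid_balance(
    state: BodyFluidState,
    na_intake: float,
    na_excretion: float,
    water_intake: float,
    urine_flow: float,
    dt_min: float,
    p: RenalParams,
    base: RenalBaseline,
) -> tuple[BodyFluidState, float]:
    """Advance whole-body Na/water balance by ``dt_min`` minutes.

    Returns the new state and the target blood volume (L) implied by the
    compliance partition.  Negative volumes are a model breakdown.
    """
    new = BodyFluidState(
        body_na=state.body_na + (na_intake - na_excretion) * dt_min,
        V_ecf=state.V_ecf + (water_intake - urine_flow) * dt_min / 1000.0,
    )
    v_b = new.blood_volume(p, base)
    if new.V_ecf <= 0 or v_b <= 0 or new.interstitial_volume(p, base) <= 0:
        raise FloatingPointError("body fluid volume became non-positive (model breakdown)")
    return new, v_b


def renal_operating_point(
    MAP: float,
    P_ven: float,
    c_na: float,
    p: RenalParams,
    base: RenalBaseline,
    at1: float = 1.0,
    mr: float = 1.0,
    anp: float = 1.0,
    vasopressin: float = 1.0,
    preaff_mult: float = 1.0,
    pt_mult: float = 1.0,
    sig_params=None,
    max_iter: int = 80,
    tol: float = 1e-11,
) -> RenalState:
    """Self-consistent renal state at a frozen hemodynamic/hormonal input.

    Damped fixed-point iteration over the three signals that close loops
    inside the kidney: TGF (macula densa flow -> afferent tone), myogenic
    (preafferent pressure -> preafferent tone) and the pressure-natriuresis
    signal (RIHP depends on peritubular pressure and distal flow, and feeds
    back on the reabsorption that sets those flows).
    """
    from .neurohormonal import SignalParams, intrinsic_signals

    sp = sig_params or SignalParams()
    mu_tgf, mu_myo, rihp_norm = 1.0, 1.0, 1.0
    vasc = None
    for _ in range(max_iter):
        vasc = renal_hemodynamics(MAP, P_ven, p, base, mu_tgf, mu_myo, at1, preaff_mult)
        gfr = glomerular_filtration(vasc.P_gc, p.P_bowman, p.pi_gc, base.K_f)
        filtered = gfr * c_na / 1000.0
        f_pt, f_cd, phi_md, _ = sodium_handling(
            filtered, p, base, at1, mr, anp, rihp_norm, pt_mult
        )
        rihp = vasc.RIHP + p.RIHP0 * p.rihp_q_gain * (phi_md / base.phi_md0 - 1.0)
        rihp = max(rihp, 0.1)
        new_rihp_norm = rihp / p.RIHP0
        new_tgf = bounded_effect(phi_md / base.phi_md0, sp.g_tgf, sp.s_tgf)
        new_myo = bounded_effect(vasc.P_preaff / base.P_pre0, sp.g_myo, sp.s_myo)
        err = abs(new_tgf - mu_tgf) + abs(new_myo - mu_myo) + abs(new_rihp_norm - rihp_norm)
        mu_tgf += 0.5 * (new_tgf - mu_tgf)
        mu_myo += 0.5 * (new_myo - mu_myo)
        rihp_norm += 0.5 * (new_rihp_norm - rihp_norm)
        if err < tol:
            break
    vasc = renal_hemodynamics(MAP, P_ven, p, base, mu_tgf, mu_myo, at1, preaff_mult)
    gfr = glomerular_filtration(vasc.P_gc, p.P_bowman, p.pi_gc, base.K_f)
    filtered = gfr * c_na / 1000.0
    f_pt, f_cd, phi_md, excretion = sodium_handling(
        filtered, p, base, at1, mr, anp, rihp_norm, pt_mult
    )
    urine = water_handling(gfr, f_pt, p, base, vasopressin)
    rihp = max(vasc.RIHP + p.RIHP0 * p.rihp_q_gain * (phi_md / base.phi_md0 - 1.0), 0.1)
    vasc.RIHP = rihp
    nephron = NephronState(
        GFR=gfr, filtered_na=filtered, f_pt=f_pt, f_ld=p.f_ld0, f_cd=f_cd,
        phi_md=phi_md, na_excretion=excretion, urine_flow=urine,
    )
    return RenalState(vasc=vasc, nephron=nephron, mu_tgf=mu_tgf, mu_myo=mu_myo,
                      rihp_norm=rihp / p.RIHP0)
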