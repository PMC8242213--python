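"""Stress-driven myocyte growth laws.

Myocytes are cylinders; the LV wall is myocytes plus fixed interstitium and
fibrosis.  Chronically elevated peak systolic fiber stress drives parallel
sarcomere addition (diameter growth, concentric remodeling); elevated
end-diastolic fiber stress drives serial addition (length growth, eccentric
remodeling).  Diameter may regress below baseline when peak stress falls
below its setpoint; length never regresses.  Growth saturates as the
increments approach their caps.  Lengthening dilates the unloaded cavity
volume with the cube of relative myocyte length.

Rates are in μm/year — remodeling lives on the months timescale and is
integrated on the slow loop with per-beat stress summaries held constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MyocyteGeometry",
    "WallComposition",
    "RemodelingParams",
    "myocyte_volume",
    "diameter_growth_rate",
    "length_growth_rate",
    "unloaded_cavity_volume",
    "lv_mass",
    "wall_composition",
    "h_over_r",
]

UM3_TO_ML = 1e-12


@dataclass
class RemodelingParams:
    """Growth-law constants.

    ``K_d0``/``K_l0`` in μm/year, stress setpoints in kPa, caps in μm.
    The diameter floor keeps regression physiologic (atrophy cannot consume
    more than half the baseline diameter).
    """

    K_d0: float = 43.8
    K_l0: float = 17.5
    sigma_peak0: float = 49.2
    sigma_ED0: float = 4.5
    dD_max: float = 25.0
    dL_max: float = 115.0
    dD_floor_frac: float = -0.5

    def __post_init__(self) -> None:
        if min(self.K_d0, self.K_l0) < 0 or min(self.sigma_peak0, self.sigma_ED0) <= 0:
            raise ValueError("rate constants must be >= 0 and setpoints > 0")
        if self.dD_max <= 0 or self.dL_max <= 0:
            raise ValueError("growth caps must be positive")


@dataclass
class MyocyteGeometry:
    """Myocyte population geometry and its remodeling increments (μm)."""

    N_myo: float = 3.3e9
    D_myo0: float = 17.26
    L_myo0: float = 115.0
    dD: float = 0.0
    dL: float = 0.0

    @property
    def D_myo(self) -> float:
        return self.D_myo0 + self.dD

    @property
    def L_myo(self) -> float:
        return self.L_myo0 + self.dL

    @property
    def V_myo(self) -> float:
        return myocyte_volume(self.N_myo, self.D_myo, self.L_myo)


@dataclass
class WallComposition:
    """LV wall volume split (mL); interstitium and fibrosis are constant."""

    V_myo: float
    V_IS: float = 26.4
    V_f: float = 4.8

    @property
    def V_w(self) -> float:
        return self.V_myo + self.V_IS + self.V_f


def myocyte_volume(N: float, D: float, L: float) -> float:
    """Total myocyte volume (mL) for N cylinders of diameter D and length L (μm)."""
    if D <= 0 or L <= 0:
        raise ValueError("myocyte dimensions must be positive")
    return N * math.pi * D * D * L / 4.0 * UM3_TO_ML


def diameter_growth_rate(sigma_peak: float, params: RemodelingParams, dD: float) -> float:
    """d(ΔD)/dt in μm/year from peak systolic fiber stress (kPa).

    Above the setpoint the rate constant tapers linearly to zero as ΔD
    approaches its cap; below the setpoint the diameter shrinks at the full
    rate constant (no floor in the law itself — the integrator applies the
    configured floor).
    """
    if sigma_peak < 0:
        raise ValueError("stress cannot be negative")
    if sigma_peak >= params.sigma_peak0:
        k_d = params.K_d0 * max(params.dD_max - dD, 0.0) / params.dD_max
    else:
        k_d = params.K_d0
    return k_d * (sigma_peak / params.sigma_peak0 - 1.0)


def length_growth_rate(sigma_ED: float, params: RemodelingParams, dL: float) -> float:
    """d(ΔL)/dt in μm/year from end-diastolic fiber stress (kPa).

    One-way ratchet: zero below the setpoint, saturating taper above it.
    """
    if sigma_ED < 0:
        raise ValueError("stress cannot be negative")
    if sigma_ED < params.sigma_ED0:
        return 0.0
    k_l = params.K_l0 * max(params.dL_max - dL, 0.0) / params.dL_max
    return k_l * (sigma_ED / params.sigma_ED0 - 1.0)


def unloaded_cavity_volume(V_LV0: float, dL: float, L_myo0: float) -> float:
    """Unloaded LV cavity volume (mL) after myocyte lengthening by dL (μm)."""
    if dL < 0:
        raise ValueError("dL cannot be negative")
    return V_LV0 * (1.0 + dL / L_myo0) ** 3


def lv_mass(V_w: float, density: float = 1.05) -> float:
    """LV mass (g) from wall volume (mL) at myocardial density (g/mL)."""
    if V_w <= 0:
        raise ValueError("wall volume must be positive")
    return V_w * density


def wall_composition(geom: MyocyteGeometry, V_IS: float = 26.4, V_f: float = 4.8) -> WallComposition:
    return WallComposition(V_myo=geom.V_myo, V_IS=V_IS, V_f=V_f)


def h_over_r(V_cav: float, V_w: float) -> float:
    """Wall-thickness-to-chamber-radius ratio for a spherical chamber."""
    r_in = (3.0 * V_cav / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_out = (3.0 * (V_cav + V_w) / (4.0 * math.pi)) ** (1.0 / 3.0)
    return (r_out - r_in) / r_in
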