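"""Lumped-parameter systemic and pulmonary circulation.

Seven compartments in a closed loop:

    LV -> arterial -> peripheral -> venous -> RV -> pulm. arterial
       -> pulm. venous -> LV

Each passive compartment has a linear pressure-volume relation
``P = (V - V0) / C``; flows obey an Ohm analogy with optional inertance on
the systemic and pulmonary arterial outflows.  Heart valves are ideal
diodes; the mitral valve may additionally carry back-leak once the reverse
pressure difference exceeds a threshold (regurgitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "COMPARTMENTS",
    "Compartment",
    "ValveSpec",
    "CirculationState",
    "compartment_pressure",
    "flow_rate_dynamics",
    "valve_flow",
    "volume_balance",
    "total_blood_volume",
]

#: canonical compartment order used throughout the package
COMPARTMENTS = ("LV", "arterial", "peripheral", "venous", "RV", "pulm_art", "pulm_ven")


@dataclass
class Compartment:
    """Passive vascular bed: equilibrium volume V0 (mL), capacitance C
    (mL/mmHg), outflow resistance R_out (mmHg·min/L) and inertance I_out
    (mmHg·min²/L, nonzero only for the two arterial beds)."""

    V0: float
    C: float
    R_out: float
    I_out: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if self.R_out <= 0:
            raise ValueError("resistance must be positive")
        if self.I_out < 0:
            raise ValueError("inertance cannot be negative")


@dataclass
class ValveSpec:
    """Ideal-diode valve, optionally leaky above a reverse-pressure threshold.

    ``leak_threshold`` is in mmHg (None for a competent valve); back-leak
    uses the forward resistance of the mitral path, ``R_leak``.
    """

    R_fwd: float
    leak_threshold: float | None = None
    R_leak: float | None = None

    def __post_init__(self) -> None:
        if self.leak_threshold is not None:
            if self.leak_threshold <= 0:
                raise ValueError("leak threshold must be positive when present")
            if self.R_leak is None:
                raise ValueError("R_leak required when a leak threshold is set")


@dataclass
class CirculationState:
    """Volumes (mL) of the seven compartments plus the two inertial flows (L/min)."""

    volumes: dict
    Q_art: float = 0.0
    Q_pulm_art: float = 0.0

    @property
    def total_volume_L(self) -> float:
        return total_blood_volume(self.volumes)


def compartment_pressure(V: float, V0: float, C: float) -> float:
    """Linear compartment pressure (mmHg); may be negative (no collapse law)."""
    if C <= 0:
        raise ValueError("capacitance must be positive")
    return (V - V0) / C


def flow_rate_dynamics(Q: float, P_up: float, P_down: float, R: float, I: float) -> float:
    """Inter-compartment flow law.

    With zero inertance the flow is algebraic and the *flow itself*
    ``(P_up - P_down)/R`` is returned; with inertance the *time derivative*
    ``dQ/dt = (P_up - P_down - R·Q)/I`` is returned (units of Q per unit of
    time implied by R and I).
    """
    if R <= 0:
        raise ValueError("resistance must be positive")
    if I == 0.0:
        return (P_up - P_down) / R
    return (P_up - P_down - R * Q) / I


def valve_flow(P_up: float, P_down: float, spec: ValveSpec) -> float:
    """Flow through an ideal-diode valve (same flow units as 1/R·mmHg).

    Forward when ``P_up > P_down``; zero in the dead band.  For a leaky
    (mitral) valve, backward flow occurs only when the reverse difference
    strictly exceeds the leak threshold.
    """
    if P_up > P_down:
        return (P_up - P_down) / spec.R_fwd
    if spec.leak_threshold is not None and (P_down - P_up) > spec.leak_threshold:
        return (P_up - P_down) / spec.R_leak  # negative (back-leak)
    return 0.0


def volume_balance(Q_in: float, Q_out: float) -> float:
    """dV/dt of a compartment from its inflow and outflow."""
    return Q_in - Q_out


def total_blood_volume(volumes: Mapping[str, float]) -> float:
    """Total blood volume (L) as the sum of all seven compartment volumes (mL)."""
    missing = set(COMPARTMENTS) - set(volumes)
    if missing:
        raise ValueError(f"missing compartments: {sorted(missing)}")
    return sum(volumes[k] for k in COMPARTMENTS) / 1000.0
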