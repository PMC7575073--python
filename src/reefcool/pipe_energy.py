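"""Pipe-flow hydraulics and the energy/cost model of a cool-water supply.

A site is supplied ``V_total`` m^3/s of cool channel water through ``n``
equal pipes of diameter ``D`` and length ``L``.  Per pipe (flow V =
V_total/n, velocity U = V/A, A = pi (D/2)^2):

    Re   = rho U D / mu                       Reynolds number
    1/sqrt(f) = -1.8 log10[((eps/D)/3.75)^1.11 + 6.9/Re]   (Haaland form)
    dp   = f rho U^2 L / (2 D)                pressure drop
    P_f  = dp V                               friction power
    P_m  = 0.5 rho V U^2                      power to accelerate the flow
    P_l  = g V (rho - rho_w) h                power to lift against buoyancy
    P_c  = c_p rho V dT                       equivalent chilling load

Site totals multiply the per-pipe powers by n; P_c uses the full site flow.
The total pumping load is P_T = P_f + P_m + P_l; P_c is reported only for
comparison (the source water is naturally cool, nothing is chilled), and is
typically more than an order of magnitude larger than P_T — which is the
whole case for pumping rather than refrigeration.  Operating cost divides by
the pump efficiency; capital cost is a flat rate per metre of pipe laid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PipeSystem",
    "FluidConstants",
    "EnergyReport",
    "RegimeError",
    "pipe_velocity",
    "reynolds",
    "friction_factor",
    "site_powers",
    "operating_cost",
    "capital_cost",
    "format_report_table",
    "TURBULENT_RE_MIN",
]

#: Below this Reynolds number the rough-pipe friction correlation is invalid.
TURBULENT_RE_MIN = 4000.0


class RegimeError(ValueError):
    """Raised when the flow is outside the turbulent rough-pipe regime."""


@dataclass(frozen=True)
class PipeSystem:
    """Geometry and flow of one injection site's pipe bundle."""

    V_total: float  # site supply [m^3/s]
    n: int = 1  # number of equal pipes
    D: float = 1.0  # pipe diameter [m]
    L: float = 3000.0  # pipe length [m]
    h: float = 40.0  # lift height / source depth [m]
    eps: float = 0.002  # wall roughness [m]

    def __post_init__(self) -> None:
        if self.V_total < 0:
            raise ValueError("V_total must be >= 0")
        for name in ("n", "D", "L", "h", "eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def V(self) -> float:
        """Flow per pipe [m^3/s]."""
        return self.V_total / self.n

    @property
    def area(self) -> float:
        """Pipe cross-sectional area [m^2]."""
        return math.pi * (self.D / 2.0) ** 2


@dataclass(frozen=True)
class FluidConstants:
    """Physical constants and unit prices.

    ``rho`` is seawater at 35 psu and 27 degC (the cool source water);
    ``rho_ambient`` the warmer water displaced at the outlet (default 35 psu
    at 28 degC), entering only the lift term.  ``cp`` is in J g^-1 degC^-1
    as conventionally tabulated and converted internally.  ``rho_cooling``
    optionally overrides the density used in the chilling-load term P_c.
    """

    rho: float = 1022.72  # kg/m^3
    rho_ambient: float = 1022.40  # kg/m^3
    mu: float = 1.08e-3  # kg s^-1 m^-1
    cp: float = 4.186  # J g^-1 degC^-1
    g: float = 9.81  # m s^-2
    efficiency: float = 0.80  # pump efficiency
    price_per_kwh: float = 1.0  # currency / kWh
    rho_cooling: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("pump efficiency must lie in (0, 1]")
        for name in ("rho", "mu", "cp", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cp_J_per_kg(self) -> float:
        return self.cp * 1000.0


@dataclass(frozen=True)
class EnergyReport:
    """Per-site hydraulics and power budget (powers in kW, site totals)."""

    U: float  # per-pipe velocity [m/s]
    Re: float
    f: float  # Darcy friction factor
    dp: float  # per-pipe pressure drop [Pa]
    P_f: float  # kW
    P_m: float  # kW
    P_l: float  # kW
    P_T: float  # kW, = P_f + P_m + P_l
    P_c: float  # kW, chilling-load equivalent (not a pumping cost)

    def __post_init__(self) -> None:
        if not math.isclose(self.P_T, self.P_f + self.P_m + self.P_l,
                            rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("P_T must equal P_f + P_m + P_l")
        if min(self.P_f, self.P_m, self.P_c) < 0:
            raise ValueError("powers must be >= 0")


def pipe_velocity(system: PipeSystem) -> float:
    """Per-pipe mean velocity U = (V_total/n) / (pi D^2/4) [m/s]."""
    return system.V / system.area


def reynolds(system: PipeSystem, fluids: FluidConstants = FluidConstants()) -> float:
    """Pipe Reynolds number rho U D / mu (turbulent above ~4000)."""
    return fluids.rho * pipe_velocity(system) * system.D / fluids.mu


def friction_factor(system: PipeSystem, Re: float, as_printed: bool = False) -> float:
    """Explicit rough-pipe (Darcy) friction factor, Haaland form.

        1/sqrt(f) = -1.8 log10[((eps/D)/3.75)^1.11 + 6.9/Re]

    Valid only for turbulent flow; raises :class:`RegimeError` below
    Re = 4000.  ``as_printed=True`` instead evaluates the same right-hand
    side as 1/f (a variant that appears in some transcriptions; it does not
    reproduce standard Moody-chart values and exists for transparency only).
    """
    if Re <= TURBULENT_RE_MIN:
        raise RegimeError(
            f"Re = {Re:.3g} is not turbulent; the rough-pipe friction "
            f"correlation requires Re > {TURBULENT_RE_MIN:g}")
    rel = (system.eps / system.D) / 3.75
    rhs = -1.8 * math.log10(rel ** 1.11 + 6.9 / Re)
    if as_printed:
        return 1.0 / rhs
    return 1.0 / rhs ** 2


def site_powers(
    system: PipeSystem,
    fluids: FluidConstants = FluidConstants(),
    dT_cool: float = 1.0,
) -> EnergyReport:
    """Full per-site power budget for one pipe bundle.

    Per-pipe friction, momentum and lift powers are multiplied by the number
    of pipes; the chilling-load comparison P_c uses the full site flow and
    ``dT_cool``.  A zero site flow yields an all-zero report.
    """
    if system.V_total == 0.0:
        return EnergyReport(U=0.0, Re=0.0, f=math.nan, dp=0.0,
                            P_f=0.0, P_m=0.0, P_l=0.0, P_T=0.0, P_c=0.0)
    U = pipe_velocity(system)
    Re = reynolds(system, fluids)
    f = friction_factor(system, Re)
    dp = f * fluids.rho * U**2 * system.L / (2.0 * system.D)  # Pa

    V = system.V
    p_f = dp * V * system.n / 1e3
    p_m = 0.5 * fluids.rho * V * U**2 * system.n / 1e3
    p_l = fluids.g * V * (fluids.rho - fluids.rho_ambient) * system.h * system.n / 1e3
    rho_c = fluids.rho_cooling if fluids.rho_cooling is not None else fluids.rho
    p_c = fluids.cp_J_per_kg * rho_c * system.V_total * dT_cool / 1e3
    return EnergyReport(U=U, Re=Re, f=f, dp=dp, P_f=p_f, P_m=p_m, P_l=p_l,
                        P_T=p_f + p_m + p_l, P_c=p_c)


def operating_cost(
    total_power_kW: float,
    efficiency: float = 0.80,
    price_per_kwh: float = 1.0,
    hours: float = 24.0,
    n_sites: int = 1,
) -> float:
    """Pumping energy cost: power x hours / efficiency x price x sites."""
    if not (0.0 < efficiency <= 1.0):
        raise ValueError("efficiency must lie in (0, 1]")
    return total_power_kW * hours / efficiency * price_per_kwh * n_sites


def capital_cost(pipe_length_m: float, rate_per_m: float = 5000.0) -> float:
    """Installed-pipe capital cost (flat rate per metre laid)."""
    if pipe_length_m < 0 or rate_per_m < 0:
        raise ValueError("inputs must be >= 0")
    return pipe_length_m * rate_per_m


def format_report_table(cases: list[tuple[PipeSystem, EnergyReport]]) -> str:
    """Plain-text table of site power budgets, one row per pipe case."""
    header = (f"{'Case V/n':>14} {'U (m/s)':>8} {'P_f (kW)':>9} "
              f"{'P_m (kW)':>9} {'P_l (kW)':>9} {'P_T (kW)':>9} {'P_c (kW)':>9}")
    lines = [header]
    for system, rep in cases:
        label = f"{system.V_total:g} m3/s / {system.n}"
        lines.append(
            f"{label:>14} {rep.U:8.2f} {rep.P_f:9.0f} {rep.P_m:9.0f} "
            f"{rep.P_l:9.0f} {rep.P_T:9.0f} {rep.P_c:9.0f}")
    return "\n".join(lines)
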