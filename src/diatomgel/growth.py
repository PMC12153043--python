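"""Force-balance growth model for walled cells dividing inside a hydrogel.

A dividing cell entrapped in a gel must push the surrounding network open.
Cavitation theory for a pressurized hole in a soft solid says the hole grows
without bound once the internal pressure exceeds a critical value of order the
elastic modulus, ``P_c ~ E*``.  Because cell expansion is slow compared with
the gel's viscoelastic/poroelastic relaxation times, the relevant stiffness is
the *residual* (long-time) modulus ``E*_inf``.  Division therefore proceeds
only while the cell's turgor pressure exceeds ``P_c(phi) = E*_inf(phi)``,
where ``phi`` is the agar concentration (% w/v) controlling gel stiffness.

Calibrated on top of this criterion are empirical two-regime laws for the
division timescale, the relative cell expansion, and the per-transition
viability of the three division transitions (first valve formation, mitotic
division, second valve formation), plus habitat conversions (hydrostatic
depth <-> pressure, nutrient diffusion timescale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GrowthParams",
    "NO_DIVISION",
    "critical_pressure",
    "residual_modulus_law",
    "can_divide",
    "division_time",
    "expansion_fraction",
    "transition_viability",
    "diffusion_time",
    "depth_pressure",
    "pressure_depth",
    "colony_capacity_mean",
    "colony_capacity_sigma",
    "colony_death_hazard",
    "packing_exponent",
]

#: Marker returned by :func:`division_time` when the gel is too stiff for the
#: cell to ever divide.  Infinity composes naturally with simulations (an
#: infinite mean division interval produces no division events).
NO_DIVISION = math.inf

# Default residual-modulus power law E*_inf(phi) = a * phi^b, calibrated so
# that E*_inf(10%) = 120 kPa with exponent 1.9 (the exponent sits in the
# 1.5-2.2 range reported for agarose gels).  Calibrated, not transcribed: the
# measured power-law coefficients are figure-embedded, only the 120 kPa value
# at 10% agar is printed.
_EINF_EXPONENT_DEFAULT = 1.9
_EINF_PREFACTOR_DEFAULT = 120.0 / 10.0**_EINF_EXPONENT_DEFAULT  # ~1.51 kPa


def _default_viability_table() -> dict[float, tuple[float, float, float]]:
    # Cumulative fraction of cells reaching transitions 1..3, at the agar
    # concentrations for which values are reported.  Interpolated linearly in
    # phi, flat below the first anchor.
    return {
        1.0: (0.89, 0.44, 0.29),
        7.0: (0.25, 0.0, 0.0),
        10.0: (0.0, 0.0, 0.0),
    }


@dataclass
class GrowthParams:
    """Calibrated parameters of the turgor-pressure growth model.

    All pressures/moduli in kPa, times in hours (simulation converts to days),
    lengths in micrometres, concentrations in % w/v agar.
    """

    # Turgor pressure: median and lognormal shape of the per-cell distribution
    P_turgor_median: float = 120.0
    P_sigma: float = 0.25
    #: order-unity prefactor in the cavitation criterion P_c = c * E*_inf
    cavitation_prefactor: float = 1.0

    # Residual-modulus power law E*_inf(phi) = a * phi^b  [kPa]
    einf_prefactor: float = _EINF_PREFACTOR_DEFAULT
    einf_exponent: float = _EINF_EXPONENT_DEFAULT

    # Two-regime division-time law: plateau below phi_crit, then linear
    # through the anchors; no division at phi >= phi_max.
    phi_crit: float = 2.0
    phi_max: float = 10.0
    t_base: float = 7.5  # h, plateau first-division time
    t_anchor: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 8.0), (7.0, 20.0))

    # Two-regime relative-expansion law (dimensionless delta_l / l0)
    e_base: float = 0.39
    e_anchor: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 0.37), (7.0, 0.09))
    expansion_floor: float = 0.0

    # Cumulative transition-viability table {phi: (v1, v2, v3)}
    viability_table: dict[float, tuple[float, float, float]] = field(
        default_factory=_default_viability_table
    )

    # Habitat hydrostatics
    depth_gradient: float = 10.0  # kPa per metre of water depth

    # Single-cell event generation
    l0_range: tuple[float, float] = (111.0, 139.0)  # um, founder-size range
    division_time_sigma: float = 0.25  # lognormal shape of transition times
    transition_time_multipliers: tuple[float, float, float] = (1.0, 0.7, 1.0)
    expansion_sd: float = 0.05  # sd of per-cell relative expansion

    # Colony-scale calibration (anchors at phi = 0.5 and 3.5 % agar):
    # mean carrying capacity, lognormal capacity shape, and the constant
    # per-colony death hazard implied by the day-21 survival fractions.
    nbar_anchor: tuple[tuple[float, float], tuple[float, float]] = ((0.5, 18.0), (3.5, 6.0))
    capacity_sigma_anchor: tuple[tuple[float, float], tuple[float, float]] = (
        (0.5, 0.30),
        (3.5, 1.00),
    )
    hazard_anchor: tuple[tuple[float, float], tuple[float, float]] = (
        (0.5, -math.log(0.80) / 21.0),
        (3.5, -math.log(0.16) / 21.0),
    )
    viable_cell_p: float = 0.78  # per-cell viability inside a living colony

    # Colony-geometry packing rule l/l0 = n^p(phi); anchors from the measured
    # (cells, size-ratio) endpoints: 18 cells -> 17.5x at 0.5%, 6 -> 2.9x at 3.5%.
    packing_anchor: tuple[tuple[float, float], tuple[float, float]] = (
        (0.5, math.log(17.5) / math.log(18.0)),
        (3.5, math.log(2.9) / math.log(6.0)),
    )
    packing_bounds: tuple[float, float] = (1.0 / 3.0, 1.0)

    def copy(self, **changes) -> "GrowthParams":
        return replace(self, **changes)


def _line_through(anchors, phi):
    """Evaluate the straight line through two (phi, y) anchor points."""
    (x0, y0), (x1, y1) = anchors
    return y0 + (y1 - y0) * (phi - x0) / (x1 - x0)


def residual_modulus_law(phi, params: GrowthParams | None = None):
    """Residual (long-time) gel modulus E*_inf(phi) in kPa, power law in phi."""
    params = params or GrowthParams()
    phi = np.asarray(phi, dtype=float)
    out = params.einf_prefactor * np.power(phi, params.einf_exponent, where=phi > 0,
                                           out=np.zeros_like(phi))
    return float(out) if out.ndim == 0 else out


def critical_pressure(Einf_star: float, prefactor: float = 1.0) -> float:
    """Critical cavitation pressure P_c = prefactor * E*_inf (kPa).

    Below P_c a pressurized hole in the gel is stable; above it the hole
    (here: the dividing cell) can grow without bound.
    """
    if Einf_star < 0:
        raise ValueError(f"Einf_star must be >= 0, got {Einf_star}")
    return prefactor * Einf_star


def can_divide(P: float, phi: float, params: GrowthParams | None = None) -> bool:
    """True iff turgor pressure P (kPa) exceeds the gel's critical pressure."""
    if P < 0:
        raise ValueError(f"turgor pressure must be >= 0, got {P}")
    params = params or GrowthParams()
    pc = critical_pressure(residual_modulus_law(phi, params), params.cavitation_prefactor)
    # strict criterion; equal pressures (within rounding) cannot open the gel
    return P - pc > 1e-9 * max(abs(pc), 1.0)


def division_time(phi: float, params: GrowthParams | None = None) -> float:
    """Mean time (h) to the first division transition at agar content phi.

    Plateau ``t_base`` below the breakpoint, linear in phi above it, and
    :data:`NO_DIVISION` (infinity) at or above ``phi_max`` where the gel's
    residual stiffness exceeds the turgor pressure.
    """
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    params = params or GrowthParams()
    if phi >= params.phi_max:
        return NO_DIVISION
    if phi <= params.phi_crit:
        return params.t_base
    return _line_through(params.t_anchor, phi)


def expansion_fraction(phi: float, params: GrowthParams | None = None) -> float:
    """Mean relative expansion delta_l / l0 during the first valve-formation
    transition: plateau below the breakpoint, linear decrease above it,
    clamped at zero and identically zero at phi >= phi_max."""
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    params = params or GrowthParams()
    if phi >= params.phi_max:
        return 0.0
    if phi <= params.phi_crit:
        return params.e_base
    return max(_line_through(params.e_anchor, phi), 0.0)


def transition_viability(phi: float, transition: int | None = None,
                         params: GrowthParams | None = None):
    """Cumulative fraction of cells reaching a division transition.

    ``transition`` is 1 (first valve formation), 2 (mitotic division) or
    3 (second valve formation); ``None`` returns all three as a tuple.
    Piecewise-linear interpolation in phi through the calibration table,
    flat below the first anchor, zero beyond the last.
    """
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    params = params or GrowthParams()
    keys = sorted(params.viability_table)
    table = np.array([params.viability_table[k] for k in keys])  # (m, 3)
    fracs = tuple(
        float(np.interp(phi, keys, table[:, j],
                        left=table[0, j],
                        right=table[-1, j]))
        for j in range(3)
    )
    if transition is None:
        return fracs
    if transition not in (1, 2, 3):
        raise ValueError(f"transition must be 1, 2 or 3, got {transition}")
    return fracs[transition - 1]


_TIME_UNITS = {"s": 1.0, "min": 60.0, "h": 3600.0, "days": 86400.0}


def diffusion_time(L: float, D: float, unit: str = "s") -> float:
    """Diffusion timescale L**2 / D.

    L in metres, D in m^2/s; result in ``unit`` ('s', 'min', 'h' or 'days').
    For a 3 mm gel and D ~ 1e-10 m^2/s this is 9e4 s, about one day -- the
    time for nutrients to reach cells at the bottom of the gel.
    """
    if L < 0:
        raise ValueError(f"L must be >= 0, got {L}")
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    try:
        scale = _TIME_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r}; choose from {sorted(_TIME_UNITS)}")
    return L * L / D / scale


def depth_pressure(depth_m: float, gradient: float = 10.0) -> float:
    """Hydrostatic pressure (kPa) at a water depth (m): ~100 kPa per 10 m."""
    if depth_m < 0:
        raise ValueError(f"depth must be >= 0, got {depth_m}")
    return gradient * depth_m


def pressure_depth(P_kpa: float, gradient: float = 10.0) -> float:
    """Water depth (m) at which hydrostatic pressure reaches P (kPa)."""
    if P_kpa < 0:
        raise ValueError(f"pressure must be >= 0, got {P_kpa}")
    return P_kpa / gradient


# -- colony-scale calibration curves ---------------------------------------

def colony_capacity_mean(phi: float, params: GrowthParams | None = None) -> float:
    """Mean colony carrying capacity (cells) at agar content phi."""
    params = params or GrowthParams()
    return max(_line_through(params.nbar_anchor, phi), 1.0)


def colony_capacity_sigma(phi: float, params: GrowthParams | None = None) -> float:
    """Lognormal shape of the capacity distribution (grows with phi: harsher
    gels amplify cell-fitness differences, widening the colony-size spread)."""
    params = params or GrowthParams()
    lo = params.capacity_sigma_anchor[0][1]
    return float(np.clip(_line_through(params.capacity_sigma_anchor, phi), lo, 2.0))


def colony_death_hazard(phi: float, params: GrowthParams | None = None) -> float:
    """Constant per-colony death hazard (1/day), linear in phi, clamped >= 0."""
    params = params or GrowthParams()
    return max(_line_through(params.hazard_anchor, phi), 0.0)


def packing_exponent(phi: float, params: GrowthParams | None = None) -> float:
    """Exponent p of the colony-geometry rule l/l0 = n_cells**p.

    p = 1 is a chain of cells, p = 1/3 a close-packed sphere; interpolated
    linearly in phi between the calibrated endpoints and clamped to [1/3, 1].
    """
    params = params or GrowthParams()
    lo, hi = params.packing_bounds
    return float(np.clip(_line_through(params.packing_anchor, phi), lo, hi))
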