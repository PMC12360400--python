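"""Krogh-cylinder oxygen transport in the capillary compartments.

Each capillary in a compartment is an identical Krogh cylinder: a vessel of
radius r_c supplying, by radial diffusion alone, a concentric tissue sleeve
of width d (outer radius r_t = r_c + d).  With a constant volumetric demand
M0 and a zero-flux outer boundary the steady radial profile has the closed
form

    P(r) = P_wall + (M0/4K)(r^2 - r_c^2) - (M0 r_t^2 / 2K) ln(r/r_c),

with K the Krogh diffusion coefficient.  The sleeve width d is set globally
from the capillary density via the volume-partition relation
CD = total capillary length / (arteriolar volume + downstream vessel+tissue
volume), solved for d by bracketed root finding.

Convective transport through a capillary loses oxygen at the constant rate
q_v = M0 pi (r_t^2 - r_c^2) per unit length (the whole sleeve consumes at
M0), so the transport rate drops linearly along the vessel and the outlet
blood PO2 follows by inverting f.  Venule compartments exchange no oxygen
(d = 0): saturation passes through unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .blood import (
    OxygenParams,
    convective_o2_rate,
    hill_saturation,
    invert_convective_o2_rate,
)
from .network import CompartmentChain
from .units import M0_TO_CGS, MM_TO_CM, NL_MIN_TO_CM3_S, UM_TO_CM

__all__ = [
    "KroghGeometry",
    "KroghProfile",
    "krogh_radial_profile",
    "tissue_width_from_density",
    "capillary_density",
    "convective_update",
    "chain_oxygen",
    "ChainOxygenResult",
    "InfeasibleDensityError",
]


class InfeasibleDensityError(ValueError):
    pass


@dataclass
class KroghGeometry:
    capillary_radius: float = 3.0  # r_c, µm
    tissue_width: float = 22.0  # d, µm
    capillary_length: float = 400.0  # µm

    def __post_init__(self):
        if self.capillary_radius <= 0 or self.tissue_width < 0:
            raise ValueError("radii must be positive, width non-negative")

    @property
    def tissue_radius(self) -> float:
        return self.capillary_radius + self.tissue_width


@dataclass
class KroghProfile:
    r: np.ndarray  # µm, [r_c, r_t]
    po2: np.ndarray  # mmHg, clamped at 0
    wall_po2: float  # mmHg
    axial_station: float  # µm along the capillary
    hypoxic: bool  # True if the unclamped form went negative


def krogh_radial_profile(
    p_wall: float,
    geom: KroghGeometry,
    m0: float,
    krogh_coeff: float = 6e-10,
    n_points: int = 50,
    axial_station: float = 0.0,
) -> KroghProfile:
    """Closed-form radial PO2 profile through the tissue sleeve.

    ``m0`` is in cm3 O2/100 cm3/min; ``krogh_coeff`` (D_diff*alpha) in
    cm3 O2/cm/s/mmHg.  Zero demand returns a flat profile at ``p_wall``.
    Values are clamped at 0 with a hypoxic-annulus flag if the analytic
    form goes negative.
    """
    if p_wall < 0:
        raise ValueError("p_wall must be >= 0")
    r_c = geom.capillary_radius * UM_TO_CM
    r_t = geom.tissue_radius * UM_TO_CM
    r = np.linspace(r_c, r_t, n_points)
    m_cgs = m0 * M0_TO_CGS
    po2 = (
        p_wall
        + m_cgs / (4.0 * krogh_coeff) * (r**2 - r_c**2)
        - m_cgs * r_t**2 / (2.0 * krogh_coeff) * np.log(r / r_c)
    )
    hypoxic = bool(np.any(po2 < 0))
    return KroghProfile(
        r=r / UM_TO_CM,
        po2=np.maximum(po2, 0.0),
        wall_po2=p_wall,
        axial_station=axial_station,
        hypoxic=hypoxic,
    )


def krogh_edge_po2(p_wall, geom: KroghGeometry, m0, krogh_coeff=6e-10):
    """PO2 at the outer tissue edge r_t (vectorized over ``p_wall``)."""
    r_c = geom.capillary_radius * UM_TO_CM
    r_t = geom.tissue_radius * UM_TO_CM
    m_cgs = m0 * M0_TO_CGS
    drop = (m_cgs / (4 * krogh_coeff) * (r_t**2 - r_c**2)
            - m_cgs * r_t**2 / (2 * krogh_coeff) * math.log(r_t / r_c))
    return np.maximum(np.asarray(p_wall, dtype=float) + drop, 0.0)


# ---------------------------------------------------------------------------
# tissue width from capillary density
# ---------------------------------------------------------------------------

def capillary_density(chains: list[CompartmentChain], vol_a_cm3: float,
                      d_um: float) -> float:
    """Capillary density (1/mm2) implied by a tissue sleeve width d."""
    num = 0.0  # total capillary length, mm
    vessel_tissue = 0.0  # downstream vessel+tissue volume, mm3
    for c in chains:
        l_c = c.capillary_length * 1e-3  # mm
        num += c.n_capillaries * l_c
        vessel_tissue += c.n_capillaries * l_c * math.pi * (
            (c.capillary_radius + d_um) * 1e-3
        ) ** 2
        vessel_tissue += (c.n_small_venules * c.small_venule_length * 1e-3
                          * math.pi * (c.small_venule_radius * 1e-3) ** 2)
        vessel_tissue += (c.n_large_venules * c.large_venule_length * 1e-3
                          * math.pi * (c.large_venule_radius * 1e-3) ** 2)
    vol_a_mm3 = vol_a_cm3 * 1e3
    return num / (vol_a_mm3 + vessel_tissue)


def tissue_width_from_density(
    chains: list[CompartmentChain],
    vol_a_cm3: float = 0.00115,
    cd_target: float = 500.0,
    d_max_um: float = 500.0,
) -> float:
    """Solve the volume-partition relation CD(d) = CD_target for d (µm).

    CD(d) is strictly decreasing in d, so the root is unique when it is
    bracketed; a target above CD(0) is infeasible for the given chains.
    """
    if cd_target <= 0:
        raise ValueError("cd_target must be > 0")
    cd0 = capillary_density(chains, vol_a_cm3, 0.0)
    if cd0 <= cd_target:
        raise InfeasibleDensityError(
            f"target CD {cd_target}/mm2 exceeds the d->0 supremum {cd0:.1f}/mm2"
        )
    f = lambda d: capillary_density(chains, vol_a_cm3, d) - cd_target
    if f(d_max_um) > 0:
        raise InfeasibleDensityError("d_max too small to bracket the root")
    return brentq(f, 0.0, d_max_um, xtol=1e-4)


# ---------------------------------------------------------------------------
# convective transport through a compartment
# ---------------------------------------------------------------------------

def convective_update(
    p_b_in: float,
    q_nl_min: float,
    geom: KroghGeometry,
    m0: float,
    params: OxygenParams,
    hematocrit: float | None = None,
):
    """Blood PO2 and saturation at the outlet of one Krogh capillary.

    Integrates df/ds = -q_v with the demand-limited constant efflux
    q_v = M0 pi (r_t^2 - r_c^2), so f_out = f_in - q_v L exactly.  A
    zero-width sleeve (venules) returns the inlet state unchanged.
    Returns (p_b_out, s_out, depleted).
    """
    if q_nl_min <= 0:
        raise ValueError("flow must be positive")
    h = params.inflow_hematocrit if hematocrit is None else hematocrit
    q_cgs = q_nl_min * NL_MIN_TO_CM3_S
    if geom.tissue_width == 0.0 or m0 == 0.0:
        return p_b_in, float(hill_saturation(p_b_in, params)), False
    r_c = geom.capillary_radius * UM_TO_CM
    r_t = geom.tissue_radius * UM_TO_CM
    q_v = m0 * M0_TO_CGS * math.pi * (r_t**2 - r_c**2)  # cm3 O2/s/cm
    f_in = float(convective_o2_rate(p_b_in, q_cgs, h, params))
    f_out = f_in - q_v * geom.capillary_length * UM_TO_CM
    if f_out <= 0.0:
        return 0.0, 0.0, True
    p_out = float(invert_convective_o2_rate(f_out, q_cgs, h, params,
                                            p_guess=p_b_in))
    return p_out, float(hill_saturation(p_out, params)), False


@dataclass
class ChainOxygenResult:
    terminal_id: int
    capillary_outlet_po2: float  # mmHg, downstream end of the capillaries
    capillary_outlet_saturation: float
    venous_outlet_saturation: float  # unchanged through SV/LV (no exchange)
    tissue_edge_po2: float  # mmHg at r_t, downstream end
    profile: KroghProfile
    depleted: bool


def chain_oxygen(
    chain: CompartmentChain,
    p_b_in: float,
    params: OxygenParams,
    tissue_width: float,
    per_capillary_flow: float | None = None,
    hematocrit: float | None = None,
) -> ChainOxygenResult:
    """Oxygen state through one compartment chain.

    All capillaries in a compartment are identical, so a single convective
    update gives the downstream PO2 shared by every capillary; the venule
    stages pass saturation through unchanged.  The returned radial profile
    is evaluated at the downstream end of the capillary.
    """
    q_cap = (chain.inflow / chain.n_capillaries
             if per_capillary_flow is None else per_capillary_flow)
    geom = KroghGeometry(
        capillary_radius=chain.capillary_radius,
        tissue_width=tissue_width,
        capillary_length=chain.capillary_length,
    )
    p_out, s_out, depleted = convective_update(
        p_b_in, q_cap, geom, params.m0, params, hematocrit=hematocrit
    )
    profile = krogh_radial_profile(
        p_out, geom, params.m0, params.krogh_coeff,
        axial_station=chain.capillary_length,
    )
    return ChainOxygenResult(
        terminal_id=chain.terminal_id,
        capillary_outlet_po2=p_out,
        capillary_outlet_saturation=s_out,
        venous_outlet_saturation=s_out,
        tissue_edge_po2=float(profile.po2[-1]),
        profile=profile,
        depleted=depleted,
    )
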