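"""Arteriolar flow regulation: vessel-wall mechanics and smooth-muscle tone.

Each arteriole carries a diameter D and a smooth-muscle activation A that
relax toward mechanical equilibrium under the Law of Laplace: the
circumferential tension T = (P - IOP) D / 2 set by the transmural pressure
must balance the wall tension T_total(D, A), the sum of an exponential
passive component and an activation-scaled Gaussian active component.  The
target activation is a sigmoid of the tone stimulus

    S_tone = C_myo T - C_shear tau_wall - C_meta S_meta + C''_tone,

combining the myogenic (pressure), shear-dependent (flow) and conducted
metabolic (PO2) responses.  Diameter and activation evolve as

    dD/dt = (1/tau_d) (D_c/T_c) (T - T_total),
    dA/dt = (1/tau_a) (A_total - A),

with the network flows re-solved after every step, iterated to steady
state.  Capillaries and venule compartments are not regulated.

The conducted metabolic signal S_meta is not specified by the wall
mechanics literature this model draws on; here it is reconstructed as a
flow-weighted sum, over the terminal pathways downstream of a vessel, of
capillary-bed hemoglobin desaturation times capillary length, decaying
exponentially with conducted distance.  This is a model reconstruction,
exposed behind `metabolic_signal` so alternatives can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .blood import OxygenParams, hill_saturation
from .hemodynamics import (
    FlowSolverConfig,
    compute_flows,
    solve_pressures,
    update_hematocrit_viscosity,
)
from .krogh import KroghGeometry, convective_update
from .network import CompartmentChain, VascularNetwork
from .units import MMHG_TO_DYN_CM2, UM_TO_CM

__all__ = [
    "RegulationParams",
    "RegulationState",
    "CalibrationError",
    "laplace_tension",
    "total_tension",
    "target_activation",
    "stimulus",
    "metabolic_signal",
    "calibrate_regulation",
    "step_regulation",
    "run_to_steady_state",
    "RegulationSummary",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class RegulationParams:
    c_shear: float = 0.0258  # cm2/dyn
    c_meta: float = 1000.0  # 1/(µM cm)
    tau_d: float = 1.0  # s
    tau_a: float = 20.0  # s
    iop: float = 15.0  # mmHg
    #: D0/Dc: passive (fully relaxed) diameter relative to the control
    #: diameter; the 1.3 default reproduces the reported 29-151 µm passive
    #: range for 22-117 µm control diameters
    d0_ratio: float = 1.3
    #: µM scale of the conducted metabolite concentration signal
    signal_conc: float = 5.0
    decay_length: float = 1.0  # cm, upstream decay of the conducted signal
    dt: float = 0.1  # s
    tol: float = 1e-6  # relative-rate steady-state tolerance
    t_max: float = 600.0  # s
    n_ox: int = 10  # steps between metabolic-signal refreshes

    def __post_init__(self):
        if self.tau_d <= 0 or self.tau_a <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class WallCoefficients:
    """Per-vessel wall-mechanics coefficients, all derived from D0 (µm)."""

    d0: np.ndarray  # µm

    def __post_init__(self):
        d0 = np.asarray(self.d0, dtype=float)
        self.c_myo = 1.37 / d0  # cm/dyn
        self.c_pass = 1.67 * d0  # dyn/cm
        self.c_pass_p = -0.027 * d0 + 12.52
        self.c_act = 1.30 * d0**1.48  # dyn/cm
        self.c_act_p = -0.00146 * d0 + 1.13
        self.c_act_pp = -0.00146 * d0 + 0.308
        if np.any(self.c_act_pp <= 0):
            raise CalibrationError("active tension range non-positive "
                                   "(D0 too large)")


@dataclass
class RegulationState:
    """Per-arteriole state and calibration, aligned with ``net.segments``."""

    diameter: np.ndarray  # D, µm
    activation: np.ndarray  # A in [0, 1]
    coeffs: WallCoefficients
    control_diameter: np.ndarray  # Dc, µm
    control_tension: np.ndarray  # Tc, dyn/cm
    c_tone: np.ndarray  # C''_tone, calibrated so control is an equilibrium
    s_meta: np.ndarray  # µM cm

    def copy(self) -> "RegulationState":
        return RegulationState(
            diameter=self.diameter.copy(),
            activation=self.activation.copy(),
            coeffs=self.coeffs,
            control_diameter=self.control_diameter,
            control_tension=self.control_tension,
            c_tone=self.c_tone,
            s_meta=self.s_meta.copy(),
        )


# ---------------------------------------------------------------------------
# wall mechanics pieces
# ---------------------------------------------------------------------------

def laplace_tension(p_mmhg, iop_mmhg, d_um):
    """Circumferential tension T = (P - IOP) D / 2 in dyn/cm."""
    dp = (np.asarray(p_mmhg, dtype=float) - iop_mmhg) * MMHG_TO_DYN_CM2
    return dp * np.asarray(d_um, dtype=float) * UM_TO_CM / 2.0


def total_tension(d_um, activation, coeffs: WallCoefficients):
    """Passive + active wall tension T_total(D, A), dyn/cm."""
    d = np.asarray(d_um, dtype=float)
    x = d / coeffs.d0
    t_pass = coeffs.c_pass * np.exp(coeffs.c_pass_p * (x - 1.0))
    t_act = coeffs.c_act * np.exp(-(((x - coeffs.c_act_p) / coeffs.c_act_pp) ** 2))
    return t_pass + activation * t_act


def target_activation(s_tone):
    """Sigmoidal total activation A_total = 1 / (1 + exp(-S_tone))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(s_tone, dtype=float)))


def stimulus(tension, wall_shear, s_meta, coeffs: WallCoefficients, c_tone,
             params: RegulationParams):
    """Tone stimulus from myogenic, shear, and conducted metabolic inputs."""
    return (coeffs.c_myo * np.asarray(tension, dtype=float)
            - params.c_shear * np.asarray(wall_shear, dtype=float)
            - params.c_meta * np.asarray(s_meta, dtype=float)
            + c_tone)


# ---------------------------------------------------------------------------
# conducted metabolic signal
# ---------------------------------------------------------------------------

def quick_chain_saturations(
    net: VascularNetwork,
    chains: list[CompartmentChain],
    oxy: OxygenParams,
    tissue_width: float,
    terminal_po2: dict[int, float] | None = None,
) -> dict[int, float]:
    """Capillary-outlet saturation per terminal from the convective Krogh
    balance, using current terminal flows.  Arteriolar desaturation is
    ignored unless per-terminal blood PO2 values are supplied."""
    p_in_default = oxy.inlet_blood_po2()
    sat = {}
    sm = net.segment_map()
    for c in chains:
        t = sm[c.terminal_id]
        p_in = (terminal_po2 or {}).get(c.terminal_id, p_in_default)
        q_cap = abs(t.flow) / c.n_capillaries
        geom = KroghGeometry(c.capillary_radius, tissue_width, c.capillary_length)
        _, s_out, _ = convective_update(p_in, q_cap, geom, oxy.m0, oxy,
                                        hematocrit=t.hematocrit)
        sat[c.terminal_id] = s_out
    return sat


def metabolic_signal(
    net: VascularNetwork,
    chains: list[CompartmentChain],
    terminal_saturation: dict[int, float],
    params: RegulationParams,
) -> np.ndarray:
    """Conducted metabolic signal S_meta per segment, µM cm.

    Flow-weighted sum over downstream terminal pathways of capillary-bed
    desaturation (1 - S_out) times capillary length, decayed exponentially
    with the conducted distance from the sensing vessel.
    """
    lam = params.decay_length
    chain_by_term = {c.terminal_id: c for c in chains}
    acc: dict[int, float] = {}
    out = net.out_segments()
    for s in reversed(net.topological_segments()):
        if s.is_terminal:
            c = chain_by_term[s.id]
            acc[s.id] = ((1.0 - terminal_saturation[s.id])
                         * c.capillary_length * UM_TO_CM)
        else:
            total = 0.0
            q_self = max(abs(s.flow), 1e-30)
            for child in out[s.to_node]:
                w = abs(child.flow) / q_self
                decay = math.exp(-child.length * UM_TO_CM / lam)
                total += w * decay * acc[child.id]
            acc[s.id] = total
    return np.array([params.signal_conc * acc[s.id] for s in net.segments])


# ---------------------------------------------------------------------------
# calibration and time stepping
# ---------------------------------------------------------------------------

def _midpoint_pressures(net: VascularNetwork) -> np.ndarray:
    nm = net.node_map()
    return np.array([
        0.5 * (nm[s.from_node].pressure + nm[s.to_node].pressure)
        for s in net.segments
    ])


def calibrate_regulation(
    net: VascularNetwork,
    chains: list[CompartmentChain],
    oxy: OxygenParams,
    params: RegulationParams,
    tissue_width: float,
) -> RegulationState:
    """Build a regulation state whose control point is an exact equilibrium.

    The network must carry a converged control-state flow solution.  Per
    vessel: Dc and Tc are the current diameter and Laplace tension; the
    passive reference diameter is D0 = d0_ratio * Dc; the control
    activation follows from the tension balance; and C''_tone is chosen so
    the sigmoid reproduces that activation under the control stimulus.
    """
    if any(not math.isfinite(s.flow) for s in net.segments):
        raise CalibrationError("solve flows before calibrating regulation")
    dc = np.array([s.diameter for s in net.segments])
    coeffs = WallCoefficients(d0=params.d0_ratio * dc)
    p_mid = _midpoint_pressures(net)
    tc = laplace_tension(p_mid, params.iop, dc)
    if np.any(tc <= 0):
        raise CalibrationError("non-positive control tension "
                               "(midpoint pressure below IOP)")
    t_pass = total_tension(dc, 0.0, coeffs)
    t_act = total_tension(dc, 1.0, coeffs) - t_pass
    a_c = (tc - t_pass) / t_act
    bad = (a_c <= 0) | (a_c >= 1)
    if np.any(bad):
        ids = [net.segments[i].id for i in np.flatnonzero(bad)]
        raise CalibrationError(
            f"control activation outside (0, 1) for segments {ids}; "
            "adjust d0_ratio or boundary pressures"
        )
    sat = quick_chain_saturations(net, chains, oxy, tissue_width)
    s_meta = metabolic_signal(net, chains, sat, params)
    tau = np.array([s.wall_shear for s in net.segments])
    c_tone = (np.log(a_c / (1.0 - a_c)) - coeffs.c_myo * tc
              + params.c_shear * tau + params.c_meta * s_meta)
    for s, d0, t in zip(net.segments, coeffs.d0, tc):
        s.passive_diameter = float(d0)
        s.control_diameter = s.diameter
        s.control_tension = float(t)
    return RegulationState(
        diameter=dc.copy(),
        activation=np.asarray(a_c, dtype=float),
        coeffs=coeffs,
        control_diameter=dc.copy(),
        control_tension=np.asarray(tc, dtype=float),
        c_tone=np.asarray(c_tone, dtype=float),
        s_meta=s_meta,
    )


def _resolve_flows(net: VascularNetwork, cfg: FlowSolverConfig):
    update_hematocrit_viscosity(net, cfg)
    solve_pressures(net, cfg)
    compute_flows(net)


def stable_timestep(state: RegulationState, net: VascularNetwork,
                    params: RegulationParams) -> float:
    """Largest explicit-Euler step that keeps the diameter equation stable.

    The local rate of the diameter ODE is k (T - T_total) with
    k = Dc/(Tc tau_d); its stiffness is k |d(T - T_total)/dD|, dominated
    by the narrow active-tension Gaussian of the largest vessels.  Returns
    min(params.dt, 1/lambda_max).
    """
    p_mid = _midpoint_pressures(net)
    d = state.diameter
    h = 1e-3 * d
    dtot = (total_tension(d + h, state.activation, state.coeffs)
            - total_tension(d - h, state.activation, state.coeffs)) / (2 * h)
    dlap = (np.asarray(p_mid) - params.iop) * MMHG_TO_DYN_CM2 * UM_TO_CM / 2.0
    k = state.control_diameter / (state.control_tension * params.tau_d)
    lam = np.max(np.abs(k * (dlap - dtot)))
    return float(min(params.dt, 1.0 / max(lam, 1e-12)))


def regulation_rates(state: RegulationState, net: VascularNetwork,
                     params: RegulationParams):
    """(dD/dt, dA/dt) at the current state with current solved flows."""
    p_mid = _midpoint_pressures(net)
    tension = laplace_tension(p_mid, params.iop, state.diameter)
    t_total = total_tension(state.diameter, state.activation, state.coeffs)
    tau_wall = np.array([s.wall_shear for s in net.segments])
    s_tone = stimulus(tension, tau_wall, state.s_meta, state.coeffs,
                      state.c_tone, params)
    a_tot = target_activation(s_tone)
    d_dot = (state.control_diameter / state.control_tension
             * (tension - t_total) / params.tau_d)
    a_dot = (a_tot - state.activation) / params.tau_a
    return d_dot, a_dot


def step_regulation(
    state: RegulationState,
    net: VascularNetwork,
    dt: float,
    params: RegulationParams,
    flow_cfg: FlowSolverConfig,
):
    """Advance one explicit Euler step and re-solve the flows.

    The step is rejected and the local dt halved (stiffness guard) if any
    diameter would become non-positive.  Returns (d_dot, a_dot, dt_used).
    """
    d_dot, a_dot = regulation_rates(state, net, params)
    dt_used = dt
    for _ in range(30):
        d_new = state.diameter + dt_used * d_dot
        if np.all(d_new > 0):
            break
        dt_used *= 0.5
    else:
        raise RuntimeError("regulation step kept producing non-positive "
                           "diameters at vanishing dt")
    state.diameter = d_new
    state.activation = np.clip(state.activation + dt_used * a_dot, 0.0, 1.0)
    for s, d in zip(net.segments, state.diameter):
        s.diameter = float(d)
    _resolve_flows(net, flow_cfg)
    return d_dot, a_dot, dt_used


@dataclass
class RegulationSummary:
    converged: bool
    t_end: float
    steps: int
    residual_d: float  # max |dD/dt| tau_d / Dc at the end
    residual_a: float  # max |dA/dt| tau_a at the end
    trajectory: list = field(default_factory=list)  # (t, res_d, res_a)


def run_to_steady_state(
    state: RegulationState,
    net: VascularNetwork,
    chains: list[CompartmentChain],
    oxy: OxygenParams,
    params: RegulationParams,
    flow_cfg: FlowSolverConfig | None = None,
    tissue_width: float = 22.0,
    record_every: int = 25,
) -> RegulationSummary:
    """Integrate the wall-mechanics ODEs to steady state in place.

    Flows are re-solved every step; the conducted metabolic signal is
    refreshed every ``params.n_ox`` steps and once more on exit so the
    final state is self-consistent.
    """
    cfg = flow_cfg or FlowSolverConfig(linear_solver="direct")
    for s, d in zip(net.segments, state.diameter):
        s.diameter = float(d)
    _resolve_flows(net, cfg)
    t = 0.0
    steps = 0
    res_d = res_a = math.inf
    traj = []
    dt = stable_timestep(state, net, params)
    while t < params.t_max:
        if steps % params.n_ox == 0:
            sat = quick_chain_saturations(net, chains, oxy, tissue_width)
            state.s_meta = metabolic_signal(net, chains, sat, params)
        if steps % 50 == 0:
            dt = stable_timestep(state, net, params)
        d_dot, a_dot, dt_used = step_regulation(state, net, dt, params, cfg)
        t += dt_used
        steps += 1
        res_d = float(np.max(np.abs(d_dot) * params.tau_d
                             / state.control_diameter))
        res_a = float(np.max(np.abs(a_dot) * params.tau_a))
        if steps % record_every == 0:
            traj.append((t, res_d, res_a))
        if res_d < params.tol and res_a < params.tol:
            # self-consistency check with a fresh metabolic signal
            sat = quick_chain_saturations(net, chains, oxy, tissue_width)
            state.s_meta = metabolic_signal(net, chains, sat, params)
            d_dot, a_dot = regulation_rates(state, net, params)
            res_d = float(np.max(np.abs(d_dot) * params.tau_d
                                 / state.control_diameter))
            res_a = float(np.max(np.abs(a_dot) * params.tau_a))
            if res_d < 10 * params.tol and res_a < 10 * params.tol:
                return RegulationSummary(True, t, steps, res_d, res_a, traj)
    raise RuntimeError(
        f"regulation did not reach steady state by t_max={params.t_max}s: "
        f"residuals D {res_d:.2e}, A {res_a:.2e}"
    )
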