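import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import root

from retinox.blood import OxygenParams
from retinox.generate import GeneratorConfig, attach_compartments, \
    generate_arteriolar_tree
from retinox.hemodynamics import (
    FlowSolverConfig,
    compute_flows,
    iterate_flow,
    solve_pressures,
    update_hematocrit_viscosity,
)
from retinox.regulation import (
    RegulationParams,
    WallCoefficients,
    calibrate_regulation,
    laplace_tension,
    metabolic_signal,
    regulation_rates,
    run_to_steady_state,
    step_regulation,
    stimulus,
    target_activation,
    total_tension,
)
from retinox.units import MMHG_TO_DYN_CM2


@pytest.fixture
def regulated_setup():
    """Small tree with converged control flows, chains, and calibration."""
    cfg = GeneratorConfig(seed=7, n_terminals=2)
    net = generate_arteriolar_tree(cfg)
    fcfg = FlowSolverConfig(linear_solver="direct")
    iterate_flow(net, fcfg)
    chains = attach_compartments(net, cfg=cfg)
    oxy = OxygenParams(m0=2.0)
    params = RegulationParams()
    state = calibrate_regulation(net, chains, oxy, params, tissue_width=22.0)
    return net, chains, oxy, params, state, fcfg


class TestWallMechanics:
    def test_laplace_zero_at_iop(self):
        assert laplace_tension(15.0, 15.0, 50.0) == 0.0

    def test_laplace_linear_in_diameter(self):
        t1 = laplace_tension(40.0, 15.0, 50.0)
        t2 = laplace_tension(40.0, 15.0, 100.0)
        assert t2 == pytest.approx(2 * t1, rel=1e-14)

    def test_laplace_hand_unit_conversion(self):
        # P = 40 mmHg, IOP = 15 mmHg, D = 100 µm:
        # T = 25 * 1333.22 dyn/cm2 * 0.01 cm / 2
        expected = 25 * 1333.22 * 0.01 / 2
        assert laplace_tension(40.0, 15.0, 100.0) == pytest.approx(
            expected, rel=1e-12)

    def test_passive_tension_at_reference_diameter(self):
        coeffs = WallCoefficients(d0=80.0)
        t = total_tension(80.0, 0.0, coeffs)
        assert float(t) == pytest.approx(1.67 * 80.0, rel=1e-12)

    def test_passive_tension_increasing_in_diameter(self):
        coeffs = WallCoefficients(d0=80.0)
        d = np.linspace(40, 160, 50)
        t = total_tension(d, 0.0, coeffs)
        assert np.all(np.diff(t) > 0)

    def test_active_peak_at_gaussian_center(self):
        coeffs = WallCoefficients(d0=80.0)
        d_peak = 80.0 * coeffs.c_act_p
        active = (total_tension(d_peak, 1.0, coeffs)
                  - total_tension(d_peak, 0.0, coeffs))
        assert float(active) == pytest.approx(float(coeffs.c_act),
                                              rel=1e-12)

    def test_sigmoid_activation_properties(self):
        assert target_activation(0.0) == 0.5
        assert target_activation(-50.0) == pytest.approx(0.0, abs=1e-12)
        s = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(target_activation(s)
                                   + target_activation(-s), 1.0, atol=1e-14)

    def test_stimulus_signs(self):
        coeffs = WallCoefficients(d0=80.0)
        params = RegulationParams()
        base = stimulus(100.0, 0.0, 0.0, coeffs, 10.0, params)
        assert stimulus(100.0, 50.0, 0.0, coeffs, 10.0, params) < base
        assert stimulus(100.0, 0.0, 0.1, coeffs, 10.0, params) < base
        assert float(stimulus(0.0, 0.0, 0.0, coeffs, 10.0, params)) == 10.0


class TestCalibration:
    def test_control_state_is_exact_equilibrium(self, regulated_setup):
        net, chains, oxy, params, state, fcfg = regulated_setup
        d_dot, a_dot = regulation_rates(state, net, params)
        assert np.max(np.abs(d_dot) / state.control_diameter) < 1e-12
        assert np.max(np.abs(a_dot)) < 1e-12

    def test_calibrated_ranges_physiological(self, regulated_setup):
        # passive diameters, control tensions and tone constants land in
        # the published parameter ranges for 22-117 µm arterioles
        _, _, _, _, state, _ = regulated_setup
        assert state.coeffs.d0.min() >= 25 and state.coeffs.d0.max() <= 160
        assert 5 <= state.control_tension.min()
        assert state.control_tension.max() <= 250
        assert 20 <= state.c_tone.min() and state.c_tone.max() <= 250
        assert np.all((state.activation > 0) & (state.activation < 1))

    def test_metabolic_signal_decreases_upstream_of_desaturation(self,
                                                                 regulated_setup):
        net, chains, oxy, params, state, fcfg = regulated_setup
        sat_low = {c.terminal_id: 0.2 for c in chains}
        sat_high = {c.terminal_id: 0.8 for c in chains}
        s_low = metabolic_signal(net, chains, sat_low, params)
        s_high = metabolic_signal(net, chains, sat_high, params)
        assert np.all(s_low > s_high)  # desaturation raises the signal


class TestDynamics:
    def test_activation_relaxes_with_tau_a(self):
        # decoupled: dA/dt = (A_total - A)/tau_a gives exponential decay
        params = RegulationParams()
        a, a_target = 0.9, 0.4
        dt, t = 0.01, 0.0
        while t < 20.0:
            a += dt * (a_target - a) / params.tau_a
            t += dt
        expected = a_target + (0.9 - a_target) * math.exp(-20.0 / params.tau_a)
        assert a == pytest.approx(expected, rel=1e-3)

    def test_step_rejected_when_diameter_would_collapse(self, regulated_setup):
        net, chains, oxy, params, state, fcfg = regulated_setup
        # poison the state so the Euler step would cross zero: full
        # activation far above the balance tension with a huge gain
        state.activation = np.ones_like(state.activation)
        state.control_tension = state.control_tension / 1e6
        _, _, dt_used = step_regulation(state, net, 0.1, params, fcfg)
        assert dt_used < 0.1
        assert np.all(state.diameter > 0)

    def test_myogenic_constriction_direction(self):
        # single vessel, shear and metabolic responses off: raising the
        # transmural pressure raises steady-state tone (smaller diameter)
        params = RegulationParams(c_shear=0.0, c_meta=0.0)
        coeffs = WallCoefficients(d0=100.0)

        def steady_diameter(p_mmhg):
            def eqs(x):
                d, a = x
                t = laplace_tension(p_mmhg, params.iop, d)
                s = stimulus(float(t), 0.0, 0.0, coeffs, 15.0, params)
                return [float(t - total_tension(d, a, coeffs)),
                        a - float(target_activation(s))]
            sol = root(eqs, [100.0, 0.5], tol=1e-12)
            assert sol.success
            return sol.x[0]

        assert steady_diameter(60.0) < steady_diameter(40.0)


class TestSteadyState:
    def test_fixed_point_matches_algebraic_root_solve(self, regulated_setup):
        net, chains, oxy, params, state, fcfg = regulated_setup
        params = replace(params, c_meta=0.0)
        state = calibrate_regulation(net, chains, oxy, params,
                                     tissue_width=22.0)
        # perturb demand has no effect with c_meta = 0; perturb pressure
        net.inlet_pressure = 44.0
        run_to_steady_state(state, net, chains, oxy, params, flow_cfg=fcfg,
                            tissue_width=22.0)
        d_ode = state.diameter.copy()

        # independent algebraic solve of {T = T_total, A = A_total}
        nseg = len(net.segments)
        oracle_net = net.copy()

        def eqs(x):
            d, a = x[:nseg], x[nseg:]
            for s, dv in zip(oracle_net.segments, d):
                s.diameter = float(dv)
            update_hematocrit_viscosity(oracle_net, fcfg)
            solve_pressures(oracle_net, fcfg)
            compute_flows(oracle_net)
            nm = oracle_net.node_map()
            p_mid = np.array([(nm[s.from_node].pressure
                               + nm[s.to_node].pressure) / 2
                              for s in oracle_net.segments])
            tau = np.array([s.wall_shear for s in oracle_net.segments])
            t = laplace_tension(p_mid, params.iop, d)
            s_tone = stimulus(t, tau, state.s_meta, state.coeffs,
                              state.c_tone, params)
            return np.concatenate([
                (t - total_tension(d, a, state.coeffs))
                / state.control_tension,
                a - target_activation(s_tone),
            ])

        x0 = np.concatenate([state.control_diameter,
                             np.full(nseg, 0.5)])
        sol = root(eqs, x0, method="hybr", tol=1e-12)
        assert sol.success
        d_root = sol.x[:nseg]
        np.testing.assert_allclose(d_ode, d_root, rtol=1e-4)

    def test_steady_state_invariant_to_dt_halving(self, regulated_setup):
        net, chains, oxy, params, state, fcfg = regulated_setup
        oxy_hi = OxygenParams(m0=3.0)
        net2 = net.copy()
        state2 = state.copy()
        run_to_steady_state(state, net, chains, oxy_hi, params,
                            flow_cfg=fcfg, tissue_width=22.0)
        params_half = replace(params, dt=params.dt / 2)
        run_to_steady_state(state2, net2, chains, oxy_hi, params_half,
                            flow_cfg=fcfg, tissue_width=22.0)
        np.testing.assert_allclose(state.diameter, state2.diameter,
                                   rtol=1e-4)

    def test_perturbation_returns_to_fixed_point(self, regulated_setup):
        net, chains, oxy, params, state, fcfg = regulated_setup
        oxy_hi = OxygenParams(m0=3.0)
        run_to_steady_state(state, net, chains, oxy_hi, params,
                            flow_cfg=fcfg, tissue_width=22.0)
        d_star = state.diameter.copy()
        state.diameter = d_star * 1.01
        run_to_steady_state(state, net, chains, oxy_hi, params,
                            flow_cfg=fcfg, tissue_width=22.0)
        np.testing.assert_allclose(state.diameter, d_star, rtol=1e-4)

    def test_activation_stays_in_unit_interval(self, regulated_setup):
        net, chains, oxy, params, state, fcfg = regulated_setup
        oxy_hi = OxygenParams(m0=4.0)
        run_to_steady_state(state, net, chains, oxy_hi, params,
                            flow_cfg=fcfg, tissue_width=22.0)
        assert np.all((state.activation >= 0) & (state.activation <= 1))

    def test_tension_balance_at_steady_state(self, regulated_setup):
        net, chains, oxy, params, state, fcfg = regulated_setup
        oxy_hi = OxygenParams(m0=3.0)
        run_to_steady_state(state, net, chains, oxy_hi, params,
                            flow_cfg=fcfg, tissue_width=22.0)
        nm = net.node_map()
        p_mid = np.array([(nm[s.from_node].pressure
                           + nm[s.to_node].pressure) / 2
                          for s in net.segments])
        t = laplace_tension(p_mid, params.iop, state.diameter)
        t_tot = total_tension(state.diameter, state.activation, state.coeffs)
        assert np.max(np.abs(t - t_tot) / state.control_tension) < 1e-4
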